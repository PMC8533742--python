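# RDRM operator sites reported for the Deinococcus radiodurans DdrO regulon,
# with the gene each site sits upstream of and the printed position of the
# site relative to the start codon (reading direction). Rows with two sites
# in the original table appear as two rows here.
gene_id	gene_name	offset	site
DR0003	ddrC	-38	GTTATGTCAAAAACATAATC
DR0070	ddrB	-31	TGTTATGTTATTTACGTAAG
DR0100	ssb	-118	TTTTATGTCATTGACATAAT
DR0326	ddrD	-29	ATTCTGCTAAAAACAGAATA
DR0423	ddrA	-23	ATTCTGTTCTAAACTAAAT
DR0423	ddrA	-44	TTTATGTCTTGACCGTAAT
DR0596	ruvB	-28	ATTTCGCAAATAGCGTAAT
DR0906	gyrB	-157	ATTCTGTAAGAGACGTAAT
DR1039	mutS	-43	GTTTCGCTCAGAACGTAAA
DR1916	recG	-17	GTTACGCTGTGAGCGAAAT
DR1572	helD	+9	TTTATGTCTCTGGCAGAAC
DR1902	recD	-46	ATTACGCTGATGACATAAT
DR1913	gyrA	-118	ATTACGTGATTAACATAAT
DR2069	ligA	-47	ATTCTGCCCTGAACCGAAC
DR2275	uvrB	-105	CTTACGCTGTGGGCGTAAA
DR2338	cinA	-35	GTTATGCTGCTAGCAGAAA
DRA0346	pprA	-29	AATCTGTTCAGGGCATAAT
DR2574	ddrO	-153	ATTCTGTATTGACCGTAGC
DR0139	hflX	-390	GTTCTGTCCGGGGCGAAAC
DR2174	leuS	-291	CATATGTCATGAGCATAAC
DR2255	DR2255	-209	AATACGCTAGGGGCGTAAA
DR2255	DR2255	-193	ATTCCGGTAAAGACAGAAT
DR2441	ddrN	-109	AATTTGTTATTTGCGAACT
DR0217	DR0217	+4	ATTACGCCAAAGACGTGTT
DR0561	DR0561	-245	GTTCAGGAAAAAACATAAC
DR1297	DR1297	-131	GTTACGCTCCTAAACAAAT
DR2256	tkt	-182	TTTACGCCCCTAGCGTATT
DR2256	tkt	-199	ATTCTGTCTTTACCGGAAT
DRA0275	DRA0275	-93	ATGTGACAAAGAGCGTAT
DR0219	ddrF	-43	TGTTATGTTATATACGTAAA
DR0685	DR0685	-37	TCTTATGTTCTGAACGCTTT
DR1143	DR1143	-47	GTTATGTTTTAAGCGTAAA
DR1571	DR1571	-290	GTTCTGCCAGAGACATAAA
DR2173	DR2173	-17	GTTATGCTCATGACATATG
DRA0165	DRA0165	-83	GGTTATGCTATTTACATAAC
DRC0023	DRC0023	-193	CTTTGTTCTGTTAGCCTAAC
DRC0017	DRC0017	-248	TAGTATGCTTCTGGCGTAGT
DR1296	DR1296	-52	AATATGTAAATAGCATAGT
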