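# rdrmap

Mapping a bacterial transcription-factor regulon by integrating three
independent lines of genome-scale evidence: ChIP-seq binding peaks,
time-course RNA-seq de-repression patterns, and a palindromic operator
motif scanned across promoters.

## The problem

Radiation-tolerant bacteria such as *Deinococcus radiodurans* repress
their DNA-damage-response genes with a XRE-family repressor (DdrO) bound
to a 17-bp palindromic operator, the radiation/desiccation response
motif (RDRM).  Under genotoxic stress a metalloprotease (IrrE) cleaves
the repressor and the regulon is de-repressed.  Deciding which genes
truly belong to this regulon requires combining binding evidence (where
does the repressor sit?), expression evidence (which genes rise when the
repressor is depleted, and only then?), and sequence evidence (which
promoters carry the operator?).  `rdrmap` implements that integration as
a tested, reusable pipeline, together with a synthetic-study generator
so every stage can be exercised and calibrated at desk scale without
touching the original sequencing archives.

## Method overview

1. **Peak calling** (`rdrmap.peaks`): sliding windows (150 nt, step
   50 nt) are flagged when the IP coverage exceeds `T1 = 2` times the
   genome-wide mean, the log2 IP/control ratio exceeds `T2 = 1`, and the
   window clears the median windowed coverage.  Each of the three IP
   replicates is called against the Input and the Mock control; a region
   is retained only when both comparisons support it in at least 2 of 3
   replicates.  Peaks are classified intergenic / intragenic /
   tRNA-proximal by their summit.
2. **Motif discovery and scanning** (`rdrmap.motif`): MEME-style ZOOPS
   (zero-or-one occurrence per sequence) expectation-maximisation over
   both strands of the intergenic peak sequences, run with and without a
   palindromic (reverse-complement symmetry) constraint, widths 15-20;
   models are pooled and ranked by BIC.  Promoter windows -500..+100
   around every CDS start codon are scanned with each retained PSSM; the
   match p-value is the exact tail probability of the log-odds score
   under a 0-order background, computed by dynamic-programming
   convolution on a 10^4-bin score lattice, with hits kept at
   p <= 1e-4.
3. **Differential expression** (`rdrmap.diffexpr`): median-of-ratios
   size factors, pooled method-of-moments NB dispersions with a monotone
   mean-dispersion floor, and a two-group exact NB test (conditional on
   the group sums) of every time point (4, 6, 8, 16, 24 h) against the
   1 h reference in each strain.  A gene is DE at |FC| >= 2 and
   p <= 0.01.  The pattern classifier selects genes DE in at most two
   comparisons in the repressor-retaining strain (W37) but in more than
   three in the depletion strain (D37).
4. **Integration** (`rdrmap.integrate`): a peak is assigned to every
   gene whose promoter window it overlaps (both genes of a divergent
   pair); operons (co-directional runs with gaps <= 100 nt) propagate
   peak and motif evidence from head to members.  Genes with all three
   lines of evidence form list **L1**; the two-evidence combinations
   form **L2** (peak+DE), **L3** (DE+motif) and **L4** (peak+motif).

The package ships the 38 published RDRM operator sites as a fixture
(`rdrmap.motif.load_rdrm_sites`); their 17-column profile alignment is
both the default motif model planted by the simulator and the reference
for consensus checks (printed consensus `TATGYYHTTARCRKA`).

## Worked example

The numbered scripts under `analysis/` run the whole study end to end on
the synthetic fixture (seed 0; ~2 minutes on one CPU):

```bash
python analysis/01_simulate_study.py
python analysis/02_call_peaks.py
python analysis/03_discover_and_scan_motifs.py
python analysis/04_differential_expression.py
python analysis/05_integrate_regulon.py
```

which prints, stage by stage:

```
24 consensus peaks (24 intergenic), lengths 350-500 nt
planted sites covered by a peak: 25/25

4 PSSMs retained; best: width 18, IC 17.3 bits
best consensus:    TTACGYTYATRRCAKAAT
fixture consensus: TTMYGYYAWDRRCRTAA
304 promoter hits in 65 genes at p<=1e-4

29 genes match the DE-count pattern (W37<=2 and D37>3)
  regulon recovered: 29/31; confounders leaking in: 0

lists: L1=29 L2=0 L3=0 L4=11 (operon-collapsed: 24/0/0/11)
L1 vs planted regulon: recall 0.935, precision 1.0
```

Reading the output: all 25 planted operator sites sit under a retained
intergenic peak; the de novo motif matches the operator fixture; the
DE-count pattern recovers 29 of the 31 ground-truth regulon genes (the
planted 25 plus operon members) with no confounder leaking through; and
the three-evidence list L1 recovers the regulon at 0.94 recall and 1.0
precision.  The same pipeline runs on real data through the `rdrmap`
CLI (`rdrmap all --config run.yaml`), reading FASTA/GFF3, bedGraph
coverage and a count TSV.

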