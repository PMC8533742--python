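"""Genome + annotation data model, FASTA/GFF3 I/O and promoter-window extraction.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
to and from the 1-based inclusive convention of that format.  A promoter
window runs from ``upstream`` nt before the first base of the start codon
(offset 0) to ``downstream`` nt into the coding sequence, in the reading
direction of the gene, so for minus-strand genes the returned sequence is
the reverse complement of the genomic slice.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Replicon:
    """A single chromosome or plasmid."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"replicon {self.id}: invalid bases {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    """An annotated feature, half-open [start, end) on its replicon."""

    id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"  # CDS, tRNA or other
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def translation_start(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PromoterWindow:
    """Reading-direction sequence around a gene's translation start.

    ``first_offset`` is the offset (relative to the start codon, offset 0)
    of the first base of ``sequence``; offsets increase along the reading
    direction.  Windows are clipped only at replicon ends.
    """

    gene_id: str
    sequence: str
    first_offset: int
    replicon_id: str
    genomic_start: int  # half-open genomic span of the window
    genomic_end: int
    strand: str

    @property
    def last_offset(self) -> int:
        return self.first_offset + len(self.sequence) - 1

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic position of the base at a reading-direction offset."""
        if not self.first_offset <= offset <= self.last_offset:
            raise ValueError(f"offset {offset} outside window")
        if self.strand == "+":
            return self.genomic_start + (offset - self.first_offset)
        return self.genomic_end - 1 - (offset - self.first_offset)


class GenomeAnnotation:
    """Replicon sequences plus the gene models used by every stage."""

    def __init__(self, replicons: list[Replicon], genes: list[Gene]):
        self.replicons: dict[str, Replicon] = {}
        for rep in replicons:
            if rep.id in self.replicons:
                raise ValueError(f"duplicate replicon id {rep.id}")
            self.replicons[rep.id] = rep
        self.genes: list[Gene] = []
        self._by_id: dict[str, Gene] = {}
        for gene in genes:
            self.add_gene(gene)

    def add_gene(self, gene: Gene) -> None:
        if gene.replicon_id not in self.replicons:
            raise ValueError(f"gene {gene.id}: unknown replicon {gene.replicon_id}")
        if gene.end > self.replicons[gene.replicon_id].length:
            raise ValueError(f"gene {gene.id}: extends past replicon end")
        if gene.id in self._by_id:
            raise ValueError(f"duplicate gene id {gene.id}")
        self.genes.append(gene)
        self._by_id[gene.id] = gene

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def genes_on(self, replicon_id: str) -> list[Gene]:
        """Genes of one replicon sorted by start coordinate."""
        return sorted(
            (g for g in self.genes if g.replicon_id == replicon_id),
            key=lambda g: (g.start, g.end, g.id),
        )

    def cds(self) -> list[Gene]:
        return [g for g in self.genes if g.kind == "CDS"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            {r.id: r.sequence for r in self.replicons.values()}
            == {r.id: r.sequence for r in other.replicons.values()}
            and sorted(self.genes, key=lambda g: g.id)
            == sorted(other.genes, key=lambda g: g.id)
        )


# ---------------------------------------------------------------------------
# I/O

_KINDS = {"CDS": "CDS", "tRNA": "tRNA"}


def read_genome(fasta_path: str, gff_path: str) -> GenomeAnnotation:
    """Load replicon sequences (FASTA) and CDS/tRNA features (GFF3).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Features on replicons absent from the FASTA raise ``ValueError``, as do
    duplicated feature IDs.
    """
    replicons = [
        Replicon(rec.id, str(rec.seq)) for rec in SeqIO.parse(fasta_path, "fasta")
    ]
    genome = GenomeAnnotation(replicons, [])
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
            from_string=False,
        )
    except gffutils.exceptions.EmptyInputError:
        return genome  # header-only GFF: a valid, gene-less annotation
    for feat in db.all_features(order_by=("seqid", "start")):
        kind = _KINDS.get(feat.featuretype, "other")
        if feat.featuretype not in _KINDS:
            continue
        product = feat.attributes.get("product", [""])[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genome.add_gene(
            Gene(
                id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                kind=kind,
                product=product,
            )
        )
    return genome


def write_genome(genome: GenomeAnnotation, fasta_path: str, gff_path: str) -> None:
    """Write FASTA and GFF3 (1-based inclusive) for a genome annotation."""
    records = [
        SeqRecord(Seq(rep.sequence), id=rep.id, description="")
        for rep in genome.replicons.values()
    ]
    SeqIO.write(records, fasta_path, "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons.values():
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for rep_id in genome.replicons:
            for g in genome.genes_on(rep_id):
                attrs = f"ID={g.id}"
                if g.product:
                    attrs += f";product={g.product}"
                ftype = g.kind if g.kind in _KINDS else "region"
                fh.write(
                    f"{g.replicon_id}\trdrmap\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Promoter windows and intergenic regions


def promoter_window(
    gene: Gene,
    genome: GenomeAnnotation,
    upstream: int = 500,
    downstream: int = 100,
) -> PromoterWindow:
    """Extract the [-upstream, +downstream) window around the start codon.

    Windows may overlap neighbouring genes; they are clipped only at
    replicon ends, with offset bookkeeping preserved.
    """
    rep = genome.replicons[gene.replicon_id]
    if gene.strand == "+":
        g_start = max(0, gene.start - upstream)
        g_end = min(rep.length, gene.start + downstream)
        seq = rep.sequence[g_start:g_end]
        first = g_start - gene.start
    else:
        g_start = max(0, gene.end - downstream)
        g_end = min(rep.length, gene.end + upstream)
        seq = revcomp(rep.sequence[g_start:g_end])
        first = gene.end - g_end
    return PromoterWindow(
        gene_id=gene.id,
        sequence=seq,
        first_offset=first,
        replicon_id=gene.replicon_id,
        genomic_start=g_start,
        genomic_end=g_end,
        strand=gene.strand,
    )


def intergenic_regions(genome: GenomeAnnotation) -> list[tuple[str, int, int]]:
    """Complement of the union of all gene intervals, per replicon.

    Returns sorted, non-overlapping half-open intervals as
    (replicon_id, start, end) tuples.
    """
    out: list[tuple[str, int, int]] = []
    for rep_id, rep in genome.replicons.items():
        merged: list[list[int]] = []
        for g in genome.genes_on(rep_id):
            if merged and g.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], g.end)
            else:
                merged.append([g.start, g.end])
        prev = 0
        for s, e in merged:
            if s > prev:
                out.append((rep_id, prev, s))
            prev = max(prev, e)
        if prev < rep.length:
            out.append((rep_id, prev, rep.length))
    return out


def write_intergenic_bed(genome: GenomeAnnotation, path: str) -> None:
    """BED6 export of the intergenic regions."""
    with open(path, "w") as fh:
        for i, (rep, s, e) in enumerate(intergenic_regions(genome)):
            fh.write(f"{rep}\t{s}\t{e}\tintergenic_{i}\t0\t.\n")
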