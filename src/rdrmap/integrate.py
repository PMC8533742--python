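"""Multi-evidence regulon integration: peaks x DE pattern x motif -> lists.

A gene collects up to three lines of evidence: a ChIP peak overlapping its
promoter window, the time-course DE pattern (de-repressed in the depletion
strain only), and an operator-motif hit inside its own promoter window.
Genes with all three form list L1; the three two-evidence combinations
form L2 (peak + DE), L3 (DE + motif) and L4 (peak + motif).  Peak and
motif evidence propagate from an operon head to downstream members
(flagged as inherited), mirroring read-through transcription of bacterial
operons; a peak shared by two divergent genes is assigned to both, with
the partner recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Gene, GenomeAnnotation, promoter_window
from .motif import MotifHit, PSSM, iupac_consensus, pssm_from_sites
from .peaks import Peak


@dataclass
class Operon:
    """A maximal run of co-directional, closely spaced genes."""

    id: str
    gene_ids: list[str]  # ordered along the replicon
    head: str            # 5'-most gene in reading direction


def predict_operons(
    genome: GenomeAnnotation, gap_threshold: int = 100
) -> list[Operon]:
    """Partition CDS into putative operons (singletons allowed).

    Adjacent co-directional CDS with intergenic gap <= ``gap_threshold``
    are joined; the head is the 5'-most gene in reading direction (first
    for + runs, last for - runs).
    """
    operons: list[Operon] = []
    k = 0
    for rep_id in genome.replicons:
        cds = [g for g in genome.genes_on(rep_id) if g.kind == "CDS"]
        run: list[Gene] = []
        for g in cds:
            if (
                run
                and g.strand == run[-1].strand
                and g.start - run[-1].end <= gap_threshold
            ):
                run.append(g)
            else:
                if run:
                    k += 1
                    operons.append(_make_operon(run, k))
                run = [g]
        if run:
            k += 1
            operons.append(_make_operon(run, k))
    return operons


def _make_operon(run: list[Gene], k: int) -> Operon:
    ids = [g.id for g in run]
    head = ids[0] if run[0].strand == "+" else ids[-1]
    return Operon(id=f"operon_{k}", gene_ids=ids, head=head)


def assign_peaks_to_genes(
    peaks: list[Peak],
    genome: GenomeAnnotation,
    upstream: int = 500,
    downstream: int = 100,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Map peaks to genes whose promoter window they overlap (>= 1 bp).

    Returns (gene_id -> peak names, gene_id -> divergent partner).  A peak
    falling in the shared intergenic region of two divergent genes is
    assigned to both, and each records the other as its partner.
    """
    gene_peaks: dict[str, list[str]] = {}
    partners: dict[str, str] = {}
    windows = {
        g.id: promoter_window(g, genome, upstream, downstream)
        for g in genome.cds()
    }
    by_peak: dict[str, list[str]] = {}
    for p in peaks:
        for gid, win in windows.items():
            if win.replicon_id != p.replicon_id:
                continue
            if p.start < win.genomic_end and win.genomic_start < p.end:
                gene_peaks.setdefault(gid, []).append(p.name)
                by_peak.setdefault(p.name, []).append(gid)
    for _pname, gids in by_peak.items():
        for a in gids:
            for b in gids:
                if a == b:
                    continue
                ga, gb = genome.gene(a), genome.gene(b)
                divergent = (
                    ga.strand != gb.strand
                    and (ga.strand == "-") == (ga.start <= gb.start)
                )
                if divergent:
                    partners[a] = b
    return gene_peaks, partners


def build_lists(
    genome: GenomeAnnotation,
    gene_peaks: dict[str, list[str]],
    patterns: pd.DataFrame,
    motif_hits: list[MotifHit] | pd.DataFrame,
    operons: list[Operon],
    divergent_partners: dict[str, str] | None = None,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-gene evidence table with L1-L4 list assignment.

    Motif evidence requires a hit inside the gene's own promoter window at
    p <= ``p_threshold`` (a divergent partner's motif never leaks).  Operon
    propagation: non-head members inherit peak and motif evidence from
    their head, flagged ``evidence_inherited``; the head's own evidence is
    never altered.
    """
    if isinstance(motif_hits, pd.DataFrame):
        hits_df = motif_hits
    else:
        from .motif import hits_to_frame

        hits_df = hits_to_frame(motif_hits)
    gene_ids = [g.id for g in genome.cds()]
    universe = set(gene_ids)
    unknown = (set(gene_peaks) | set(hits_df.gene_id) | set(patterns.gene_id)) - (
        universe | set()
    )
    if unknown:
        raise ValueError(f"evidence refers to genes outside the annotation: "
                         f"{sorted(unknown)[:5]}...")
    hits_df = hits_df[hits_df.p_value <= p_threshold]
    best_hit = (
        hits_df.sort_values(["gene_id", "p_value", "offset"])
        .groupby("gene_id")
        .first()
        if len(hits_df)
        else pd.DataFrame()
    )
    operon_of = {}
    head_of = {}
    for op in operons:
        for g in op.gene_ids:
            operon_of[g] = op.id
            head_of[g] = op.head
    divergent_partners = divergent_partners or {}
    sel = dict(zip(patterns.gene_id, patterns.selected))
    rows = []
    for gid in gene_ids:
        own_peak = bool(gene_peaks.get(gid))
        own_motif = gid in best_hit.index if len(best_hit) else False
        head = head_of.get(gid, gid)
        inherited = False
        has_peak, has_motif = own_peak, own_motif
        if head != gid:
            head_peak = bool(gene_peaks.get(head))
            head_motif = head in best_hit.index if len(best_hit) else False
            if (head_peak and not own_peak) or (head_motif and not own_motif):
                inherited = True
            has_peak = own_peak or head_peak
            has_motif = own_motif or head_motif
        is_de = bool(sel.get(gid, False))
        n_evidence = has_peak + is_de + has_motif
        if has_peak and is_de and has_motif:
            lst = "L1"
        elif has_peak and is_de:
            lst = "L2"
        elif is_de and has_motif:
            lst = "L3"
        elif has_peak and has_motif:
            lst = "L4"
        else:
            lst = "none"
        motif_src = gid if own_motif else (head if has_motif else None)
        rows.append(
            {
                "gene_id": gid,
                "has_upstream_peak": has_peak,
                "peak_ids": ",".join(gene_peaks.get(gid, [])
                                     or (gene_peaks.get(head, []) if head != gid
                                         else [])),
                "is_de_pattern": is_de,
                "de_count_W37": int(
                    patterns.de_count_W37.get(gid, 0)
                ) if gid in patterns.index else 0,
                "de_count_D37": int(
                    patterns.de_count_D37.get(gid, 0)
                ) if gid in patterns.index else 0,
                "has_rdrm": has_motif,
                "motif_offset": (
                    int(best_hit.loc[motif_src, "offset"])
                    if motif_src is not None and len(best_hit)
                    and motif_src in best_hit.index
                    else pd.NA
                ),
                "motif_p": (
                    float(best_hit.loc[motif_src, "p_value"])
                    if motif_src is not None and len(best_hit)
                    and motif_src in best_hit.index
                    else np.nan
                ),
                "motif_site": (
                    best_hit.loc[motif_src, "letters"]
                    if motif_src is not None and len(best_hit)
                    and motif_src in best_hit.index
                    else ""
                ),
                "list": lst,
                "n_evidence": n_evidence,
                "operon_id": operon_of.get(gid, ""),
                "evidence_inherited": inherited,
                "divergent_partner": divergent_partners.get(gid, ""),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def report(
    evidence: pd.DataFrame,
    genome: GenomeAnnotation | None = None,
    candidate_peaks: list[Peak] | None = None,
    retained_peaks: list[Peak] | None = None,
) -> dict:
    """Assemble the report bundle from an evidence table.

    Returns a dict with the candidate-gene table (L1-L4 rows), per-list
    counts (raw and operon-collapsed), the IUPAC consensus of L1 motif
    sites (skipped with a warning entry when empty), and a near-miss table
    of sub-threshold candidate peaks in promoters of L3 genes.
    """
    members = evidence[evidence.list != "none"].copy()
    counts = {
        lst: int((evidence.list == lst).sum()) for lst in ("L1", "L2", "L3", "L4")
    }
    collapsed = {
        lst: int(
            members[members.list == lst]
            .apply(lambda r: r.operon_id or r.gene_id, axis=1)
            .nunique()
        )
        for lst in ("L1", "L2", "L3", "L4")
    }
    l1_sites = [
        s for s in members[members.list == "L1"].motif_site if isinstance(s, str) and s
    ]
    same_w = [s for s in l1_sites if l1_sites and len(s) == len(l1_sites[0])]
    if same_w:
        consensus = iupac_consensus(pssm_from_sites(same_w))
        warning = ""
    else:
        consensus = ""
        warning = "no L1 motif sites; consensus skipped"
    near_miss = pd.DataFrame(
        columns=["gene_id", "peak_replicon", "peak_start", "peak_end", "mean_ip"]
    )
    if candidate_peaks and genome is not None:
        retained_names = {p.name for p in (retained_peaks or [])}
        sub = [p for p in candidate_peaks if p.name not in retained_names]
        l3 = members[members.list == "L3"].gene_id.tolist()
        rows = []
        for gid in l3:
            win = promoter_window(genome.gene(gid), genome)
            for p in sub:
                if (
                    p.replicon_id == win.replicon_id
                    and p.start < win.genomic_end
                    and win.genomic_start < p.end
                ):
                    rows.append(
                        {
                            "gene_id": gid,
                            "peak_replicon": p.replicon_id,
                            "peak_start": p.start,
                            "peak_end": p.end,
                            "mean_ip": p.mean_ip,
                        }
                    )
        if rows:
            near_miss = pd.DataFrame(rows)
    return {
        "table": members,
        "counts": counts,
        "counts_operon_collapsed": collapsed,
        "l1_consensus": consensus,
        "warning": warning,
        "near_miss": near_miss,
    }
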