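"""Synthetic study generator: genome, planted regulon, ChIP tracks, counts.

The generator emulates the structure the analysis assumes: a small
multi-replicon bacterial genome; a regulon of genes carrying one
palindromic operator site each in their upstream intergenic region; ChIP
coverage in which immunoprecipitated (IP) replicates are enriched at the
planted sites over a bumpy shared background while Mock and Input
controls are background-only; and a negative-binomial count matrix for
two strains x six time points x three replicates in which regulon genes
rise only in the depletion strain (D37) while "confounder" genes respond
in both strains.  Everything is reproducible bit-for-bit from one seed,
and a GroundTruth object records what was planted so every downstream
stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Gene, GenomeAnnotation, Replicon, revcomp, write_genome
from .motif import PSSM, load_rdrm_sites, align_sites
from .peaks import CoverageTrack, write_bedgraph

DEFAULT_TIMES = (1, 4, 6, 8, 16, 24)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    The defaults reproduce the design of the emulated study: 300 genes on
    three replicons, a 25-gene planted regulon whose operator sites are
    17-mers drawn from the packaged fixture, 10% confounder genes
    deregulated in both strains, 8x ChIP enrichment over a background of
    5 reads/nt, and a fold-change trajectory that increases through the
    time course in the depletion strain only.
    """

    seed: int = 0
    n_genes: int = 300
    replicon_lengths: tuple[int, ...] = (220_000, 90_000, 45_000)
    regulon_size: int = 25
    motif_model: object | None = None  # PSSM, list of literal sites, or None
    # gene placement
    gene_length_range: tuple[int, int] = (300, 2400)
    mean_gap: int = 200
    min_gap: int = 50
    operon_pair_prob: float = 0.25
    strand_persistence: float = 0.6
    trna_fraction: float = 0.02
    site_offset_range: tuple[int, int] = (-300, -15)
    min_regulon_gap: int = 120
    # plant only sites detectable at the study's scan threshold under the
    # fixture PSSM (the regulon table being emulated is operationally
    # defined by scanner-detected sites); None disables the conditioning
    site_detectability_p: float | None = 1e-4
    # ChIP model
    chip_enrichment_fold: float = 8.0
    fragment_size: int = 200
    background_rate: float = 5.0
    background_roughness: float = 0.25
    block_size: int = 500
    n_ip_replicates: int = 3
    # RNA-seq model
    nb_base_mean_lognormal: tuple[float, float] = (np.log(150.0), 1.0)
    nb_dispersion_range: tuple[float, float] = (0.05, 0.15)
    regulon_fc_trajectory: dict = field(
        default_factory=lambda: {1: 1.0, 4: 2.0, 6: 4.0, 8: 8.0, 16: 8.0, 24: 8.0}
    )
    confounder_fc_trajectory: dict = field(
        default_factory=lambda: {1: 1.0, 4: 3.0, 6: 5.0, 8: 5.0, 16: 4.0, 24: 3.0}
    )
    confounder_fraction: float = 0.10
    library_size_range: tuple[float, float] = (0.7, 1.4)
    times: tuple[int, ...] = DEFAULT_TIMES
    strains: tuple[str, ...] = ("W37", "D37")
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.regulon_size > self.n_genes:
            raise ValueError("regulon_size must not exceed n_genes")
        for traj in (self.regulon_fc_trajectory, self.confounder_fc_trajectory):
            if traj and traj.get(1) != 1.0:
                raise ValueError("trajectory value at t=1 h must equal 1")
            if any(v <= 0 for v in traj.values()):
                raise ValueError("fold changes must be > 0")
        if self.background_rate <= 0 or self.chip_enrichment_fold <= 0:
            raise ValueError("rates and folds must be > 0")


@dataclass
class PlantedSite:
    replicon_id: str
    position: int  # 0-based genomic start of the site
    strand: str    # strand of the site relative to the gene's reading direction
    gene_id: str
    offset: int    # reading-direction offset of the site's 5'-most base
    sequence: str  # site in gene reading direction


@dataclass
class GroundTruth:
    regulon_gene_ids: list[str]
    planted_sites: list[PlantedSite]
    confounder_gene_ids: list[str]
    planted_pssm: PSSM | None = None


def _fixture_sites() -> list[str]:
    return align_sites(load_rdrm_sites()["site"].tolist(), width=17)


def _make_site_drawer(model, p_max: float | None):
    """Site sampler, optionally conditioned on scanner detectability."""
    if p_max is None:
        if isinstance(model, PSSM):
            return lambda rng: model.sample_site(rng)
        return lambda rng: model[int(rng.integers(len(model)))]
    from .motif import pssm_from_sites, score_pvalues, rdrm_fixture_pssm

    ref = model if isinstance(model, PSSM) else pssm_from_sites(model)
    dist = score_pvalues(ref)
    if isinstance(model, PSSM):
        def draw(rng, _dist=dist, _model=model):
            for _ in range(200):
                s = _model.sample_site(rng)
                if _dist.pvalue_of_word(s) <= p_max:
                    return s
            raise ValueError("could not draw a detectable site from the PSSM")
        return draw
    pool = [s for s in model if dist.pvalue_of_word(s) <= p_max]
    if not pool:
        raise ValueError("no literal site is detectable at the given threshold")
    return lambda rng: pool[int(rng.integers(len(pool)))]


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Generate the genome, annotation and planted regulon.

    Genes are laid down left to right with geometric intergenic gaps
    (minimum ``min_gap``); strand choice is persistent so co-directional
    runs (candidate operons) and divergent pairs both occur, and a
    fraction of co-directional neighbours are placed at operon-like short
    gaps.  One operator site is planted per regulon gene in its upstream
    intergenic gap, on either strand.  Regulon genes are drawn among
    operon-head or singleton CDS with enough upstream room; their
    co-directional downstream operon members join the ground-truth regulon
    (read-through co-transcription).
    """
    rng = np.random.default_rng(config.seed)
    sites_model = config.motif_model or _fixture_sites()
    draw_site = _make_site_drawer(sites_model, config.site_detectability_p)
    site_w = (
        sites_model.width
        if isinstance(sites_model, PSSM)
        else len(sites_model[0])
    )

    seqs = {
        f"rep{i + 1}": rng.integers(0, 4, size=n)
        for i, n in enumerate(config.replicon_lengths)
    }
    bases = np.array(list("ACGT"))

    genes: list[Gene] = []
    upstream_gap: dict[str, int] = {}  # reading-direction upstream intergenic gap
    gi = 0
    lo_len, hi_len = config.gene_length_range
    for rep_id, n in ((r, len(s)) for r, s in seqs.items()):
        pos = int(config.min_gap)
        prev_strand = "+" if rng.random() < 0.5 else "-"
        prev_gap = pos
        while gi < config.n_genes:
            length = int(
                np.clip(rng.lognormal(np.log(800), 0.45), lo_len, hi_len)
            )
            if rng.random() < config.trna_fraction:
                length, kind = 80, "tRNA"
            else:
                kind = "CDS"
            if pos + length + config.min_gap > n:
                break
            if rng.random() < config.strand_persistence:
                strand = prev_strand
            else:
                strand = "-" if prev_strand == "+" else "+"
            gi += 1
            gene = Gene(
                id=f"g{gi:04d}",
                replicon_id=rep_id,
                start=pos,
                end=pos + length,
                strand=strand,
                kind=kind,
                product=f"synthetic protein {gi}",
            )
            genes.append(gene)
            if strand == "+":
                upstream_gap[gene.id] = prev_gap
            # gap to the next gene
            if strand == prev_strand and rng.random() < config.operon_pair_prob:
                gap = int(rng.integers(20, 81))
            else:
                gap = config.min_gap + int(rng.geometric(1.0 / config.mean_gap))
            if strand == "-":
                upstream_gap[gene.id] = gap
            prev_strand = strand
            prev_gap = gap
            pos += length + gap
        if gi >= config.n_genes:
            break
    if gi < config.n_genes:
        raise ValueError(
            f"replicons too small: placed {gi} of {config.n_genes} genes"
        )

    genome = GenomeAnnotation(
        [Replicon(r, "".join(bases[s])) for r, s in seqs.items()], []
    )
    for g in genes:
        genome.add_gene(g)

    # operon structure (local, same rule as the integration default)
    from .integrate import predict_operons

    operons = predict_operons(genome, gap_threshold=100)
    head_of = {}
    members_of = {}
    for op in operons:
        members_of[op.head] = [g for g in op.gene_ids if g != op.head]
        for g in op.gene_ids:
            head_of[g] = op.head

    candidates = [
        g.id
        for g in genome.cds()
        if head_of.get(g.id, g.id) == g.id
        and upstream_gap.get(g.id, 0) >= max(config.min_regulon_gap, site_w + 25)
    ]
    if config.regulon_size > len(candidates):
        raise ValueError(
            f"regulon_size {config.regulon_size} exceeds {len(candidates)} "
            "available promoters"
        )
    heads = sorted(
        rng.choice(candidates, size=config.regulon_size, replace=False).tolist()
    )

    planted: list[PlantedSite] = []
    seq_arrays = {r: np.array(list(genome.replicons[r].sequence)) for r in seqs}
    occupied: dict[str, list[tuple[int, int]]] = {r: [] for r in seqs}
    off_lo, off_hi = config.site_offset_range
    for gid in heads:
        gene = genome.gene(gid)
        gap = upstream_gap[gid]
        lo = max(off_lo, -(gap - site_w))
        offset = int(rng.integers(lo, off_hi + 1))
        # avoid clobbering a site already planted in a shared intergenic gap
        for _try in range(20):
            if gene.strand == "+":
                cand = gene.start + offset
            else:
                cand = gene.end - offset - site_w
            if all(
                cand + site_w <= s or e <= cand
                for s, e in occupied[gene.replicon_id]
            ):
                break
            offset = int(rng.integers(lo, off_hi + 1))
        site = draw_site(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = site if strand == "+" else revcomp(site)
        if gene.strand == "+":
            g_start = gene.start + offset
            genomic = oriented
        else:
            g_start = gene.end - offset - site_w
            genomic = revcomp(oriented)
        arr = seq_arrays[gene.replicon_id]
        arr[g_start : g_start + site_w] = list(genomic)
        occupied[gene.replicon_id].append((g_start, g_start + site_w))
        planted.append(
            PlantedSite(
                replicon_id=gene.replicon_id,
                position=g_start,
                strand=strand,
                gene_id=gid,
                offset=offset,
                sequence=oriented,
            )
        )
    for rep_id, arr in seq_arrays.items():
        genome.replicons[rep_id].sequence = "".join(arr)

    regulon = sorted(
        set(heads) | {m for h in heads for m in members_of.get(h, [])}
    )
    non_regulon = [
        g.id for g in genome.cds() if g.id not in set(regulon)
    ]
    n_conf = int(round(config.confounder_fraction * config.n_genes))
    confounders = sorted(
        rng.choice(non_regulon, size=min(n_conf, len(non_regulon)), replace=False)
        .tolist()
    )
    truth = GroundTruth(
        regulon_gene_ids=regulon,
        planted_sites=planted,
        confounder_gene_ids=confounders,
        planted_pssm=sites_model if isinstance(sites_model, PSSM) else None,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# ChIP coverage


def simulate_chip(
    genome: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> dict[str, CoverageTrack]:
    """Per-base coverage for IP replicates, Input and Mock.

    The background is a bumpy Poisson field: each 500-nt block carries a
    Gamma-distributed regional rate (mean ``background_rate``) shared by
    the IP and Mock samples; the Input re-uses each block's quantile at
    half the roughness.  IP samples add a triangular enrichment kernel of
    half-width ``fragment_size`` and peak height (fold - 1) * background
    at each planted site midpoint before Poisson sampling.
    """
    rng = np.random.default_rng(config.seed + 1)
    r = config.background_roughness
    bg = config.background_rate
    rates: dict[str, np.ndarray] = {}
    rates_input: dict[str, np.ndarray] = {}
    for rep_id, rep in genome.replicons.items():
        n_blocks = int(np.ceil(rep.length / config.block_size))
        u = rng.random(n_blocks)
        lam = stats.gamma.ppf(u, a=1.0 / r, scale=bg * r)
        lam_in = stats.gamma.ppf(u, a=2.0 / r, scale=bg * r / 2.0)
        rates[rep_id] = np.repeat(lam, config.block_size)[: rep.length]
        rates_input[rep_id] = np.repeat(lam_in, config.block_size)[: rep.length]

    kernel_by_rep: dict[str, np.ndarray] = {
        rep_id: np.zeros(rep.length) for rep_id, rep in genome.replicons.items()
    }
    height = (config.chip_enrichment_fold - 1.0) * bg
    half = config.fragment_size
    for site in truth.planted_sites:
        arr = kernel_by_rep[site.replicon_id]
        center = site.position + len(site.sequence) // 2
        lo = max(0, center - half)
        hi = min(arr.size, center + half + 1)
        x = np.arange(lo, hi)
        arr[lo:hi] += height * (1.0 - np.abs(x - center) / half).clip(min=0)

    tracks: dict[str, CoverageTrack] = {}
    for i in range(config.n_ip_replicates):
        tracks[f"IP{i + 1}"] = CoverageTrack(
            f"IP{i + 1}",
            {
                rep_id: rng.poisson(rates[rep_id] + kernel_by_rep[rep_id]).astype(
                    float
                )
                for rep_id in rates
            },
        )
    tracks["Mock"] = CoverageTrack(
        "Mock", {rep_id: rng.poisson(rates[rep_id]).astype(float) for rep_id in rates}
    )
    tracks["Input"] = CoverageTrack(
        "Input",
        {rep_id: rng.poisson(rates_input[rep_id]).astype(float) for rep_id in rates},
    )
    return tracks


def export_fragments(
    track: CoverageTrack, config: SimulationConfig, path: str, seed: int = 0
) -> None:
    """Approximate fragment-level BED export for interface realism.

    Fragment starts are drawn proportional to local coverage; piling the
    exported fragments reproduces the track only up to sampling noise.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for rep_id, arr in track.data.items():
            n_frag = int(arr.sum() / config.fragment_size)
            if n_frag == 0 or arr.sum() == 0:
                continue
            p = arr / arr.sum()
            centers = rng.choice(arr.size, size=n_frag, p=p)
            for j, c in enumerate(np.sort(centers)):
                s = max(0, int(c) - config.fragment_size // 2)
                e = min(arr.size, int(c) + config.fragment_size // 2)
                fh.write(f"{rep_id}\t{s}\t{e}\t{track.sample_id}_f{j}\n")


# ---------------------------------------------------------------------------
# RNA-seq counts


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for strain in config.strains:
        for time in config.times:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{strain}_t{time}_r{rep}",
                        "strain": strain,
                        "time": time,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    genome: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix (genes x samples) plus its sample sheet.

    Gene base means are log-normal; per-sample means are base mean x
    library factor x fold change, where regulon genes follow the regulon
    trajectory in D37 only and confounder genes follow the confounder
    trajectory in both strains (alternating up/down per gene).  Counts are
    NB with per-gene dispersion drawn uniformly from
    ``nb_dispersion_range``.
    """
    rng = np.random.default_rng(config.seed + 2)
    meta = sample_sheet(config)
    gene_ids = [g.id for g in genome.cds()]
    n = len(gene_ids)
    mu_log, sigma_log = config.nb_base_mean_lognormal
    base = rng.lognormal(mu_log, sigma_log, size=n)
    alpha = rng.uniform(*config.nb_dispersion_range, size=n)
    lib = rng.uniform(*config.library_size_range, size=len(meta))

    regulon = set(truth.regulon_gene_ids)
    confounders = {
        g: (+1 if i % 2 == 0 else -1)
        for i, g in enumerate(truth.confounder_gene_ids)
    }
    fc = np.ones((n, len(meta)))
    for j, row in meta.iterrows():
        t = int(row.time)
        for i, g in enumerate(gene_ids):
            if g in regulon and row.strain == "D37":
                fc[i, j] = config.regulon_fc_trajectory.get(t, 1.0)
            elif g in confounders:
                f = config.confounder_fc_trajectory.get(t, 1.0)
                fc[i, j] = f if confounders[g] > 0 else 1.0 / f
    mean = base[:, None] * lib[None, :] * fc
    size = 1.0 / alpha
    counts = rng.negative_binomial(size[:, None], size[:, None] / (size[:, None] + mean))
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=meta["sample"])
    return df, meta


# ---------------------------------------------------------------------------
# Fixture directory export


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "kind": "site",
            "gene_id": s.gene_id,
            "replicon": s.replicon_id,
            "position": s.position,
            "strand": s.strand,
            "offset": s.offset,
            "sequence": s.sequence,
        }
        for s in truth.planted_sites
    ]
    rows += [
        {"kind": "regulon", "gene_id": g} for g in truth.regulon_gene_ids
    ]
    rows += [
        {"kind": "confounder", "gene_id": g} for g in truth.confounder_gene_ids
    ]
    return pd.DataFrame(rows)


def write_fixture(
    outdir, genome: GenomeAnnotation, truth: GroundTruth,
    tracks: dict[str, CoverageTrack], counts: pd.DataFrame, meta: pd.DataFrame,
    config: SimulationConfig, header: str = "",
) -> None:
    """Write the complete synthetic study to a directory of text files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    write_genome(genome, p("genome.fasta"), p("annotation.gff3"))
    for name, track in tracks.items():
        write_bedgraph(track, p(f"coverage_{name}.bedgraph"), header=header)
    export_fragments(
        tracks["IP1"], config, p("fragments_IP1.bed"), seed=config.seed + 3
    )
    counts.to_csv(p("counts.tsv"), sep="\t")
    meta.to_csv(p("samples.tsv"), sep="\t", index=False)
    truth_to_frame(truth).to_csv(p("ground_truth.tsv"), sep="\t", index=False)
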