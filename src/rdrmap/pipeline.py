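"""End-to-end orchestration of the regulon-mapping pipeline.

Stages: synthetic-study generation (or loading of user inputs), ChIP peak
calling against both controls, motif discovery from retained intergenic
peak sequences, promoter scanning, time-course differential expression
with pattern classification, and integration into the L1-L4 candidate
lists.  ``run_all`` executes the full chain in memory and persists every
stage's outputs; all randomness flows from one root seed and every output
file starts with a comment header carrying the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, genome as genome_io, integrate, motif, peaks, simulate

logger = logging.getLogger("rdrmap")


@dataclass
class RunConfig:
    """Paths, thresholds and the root seed for one pipeline run."""

    output_dir: str = "rdrmap_out"
    genome_fasta: str | None = None
    genome_gff: str | None = None
    coverage: dict = field(default_factory=dict)  # sample -> bedGraph path
    counts: str | None = None
    samples: str | None = None
    seed: int = 0
    # stage parameters
    peak_params: dict = field(default_factory=dict)
    motif_widths: tuple[int, int] = (15, 20)
    motif_mode: str = "both"
    motif_n_starts: int = 10
    motif_p_threshold: float = 1e-4
    de_params: dict = field(default_factory=dict)
    operon_gap: int = 100
    promoter_upstream: int = 500
    promoter_downstream: int = 100
    apply_intermediate_filter: bool = False
    skip_motif: bool = False
    simulation: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("motif_widths",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    _PATH_FIELDS = ("output_dir", "genome_fasta", "genome_gff", "coverage",
                    "counts", "samples")

    def config_hash(self) -> str:
        """Hash of the scientific parameters only (paths excluded), so the
        same analysis re-run in a different directory hashes identically."""
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"# rdrmap config_hash={self.config_hash()} seed={self.seed}\n"


def _write_table(df: pd.DataFrame, path: str, config: RunConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(config.header())
        df.to_csv(fh, sep="\t", **kw)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig):
    """Generate the synthetic study and write it under output_dir/fixture."""
    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    genome, truth = simulate.simulate_genome(sim_cfg)
    tracks = simulate.simulate_chip(genome, truth, sim_cfg)
    counts, meta = simulate.simulate_counts(genome, truth, sim_cfg)
    outdir = os.path.join(config.output_dir, "fixture")
    simulate.write_fixture(
        outdir, genome, truth, tracks, counts, meta, sim_cfg,
        header=config.header(),
    )
    logger.info("simulate: %d genes, %d planted sites -> %s",
                len(genome.genes), len(truth.planted_sites), outdir)
    return genome, truth, tracks, counts, meta


def load_inputs(config: RunConfig):
    genome = genome_io.read_genome(config.genome_fasta, config.genome_gff)
    lengths = {r.id: r.length for r in genome.replicons.values()}
    tracks = {
        name: peaks.read_bedgraph(path, name, lengths)
        for name, path in config.coverage.items()
    }
    counts = pd.read_csv(config.counts, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(config.samples, sep="\t", comment="#")
    return genome, tracks, counts, meta


def stage_callpeaks(config: RunConfig, genome, tracks):
    """Call peaks per replicate against both controls and retain consensus."""
    params = peaks.PeakParams(**config.peak_params)
    ip_names = sorted(n for n in tracks if n.startswith("IP"))
    order = ip_names + ["Input", "Mock"]
    normed = dict(
        zip(order, peaks.normalize_tracks([tracks[n] for n in order]))
    )
    vs_input = [
        peaks.call_peaks_one(normed[n], normed["Input"], params) for n in ip_names
    ]
    vs_mock = [
        peaks.call_peaks_one(normed[n], normed["Mock"], params) for n in ip_names
    ]
    mean_ip = peaks.CoverageTrack(
        "mean_IP",
        {
            rep: np.mean([normed[n].data[rep] for n in ip_names], axis=0)
            for rep in genome.replicons
        },
    )
    retained = peaks.retain_consensus_peaks(vs_input, vs_mock, params, mean_ip)
    retained = peaks.classify_peaks(retained, genome)
    candidates = [p for lst in vs_input + vs_mock for p in lst]
    for i, p in enumerate(candidates):
        p.name = p.name or f"candidate_{i + 1}"
    os.makedirs(config.output_dir, exist_ok=True)
    peaks.write_peaks_bed(
        retained, os.path.join(config.output_dir, "peaks.bed"),
        header=config.header(),
    )
    _write_table(
        peaks.peaks_to_frame(retained),
        os.path.join(config.output_dir, "peaks.tsv"), config, index=False,
    )
    logger.info("callpeaks: %d consensus peaks (%d intergenic)",
                len(retained),
                sum(p.location == "intergenic" for p in retained))
    return retained, candidates


def stage_discover(config: RunConfig, genome, retained):
    """Discover motifs from intergenic retained-peak sequences."""
    promoter_like = [
        p for p in retained if p.location in ("intergenic", "tRNA-proximal")
    ]
    seqs = peaks.peak_sequences(promoter_like, genome)
    results = motif.discover_motifs(
        seqs,
        width_range=config.motif_widths,
        mode=config.motif_mode,
        n_starts=config.motif_n_starts,
        seed=config.seed,
    )
    pssms = [r.pssm for r in results]
    motif.write_meme(pssms, os.path.join(config.output_dir, "motifs.meme"))
    logger.info("discover: %d motifs, best width %d (BIC %.1f)",
                len(results), results[0].pssm.width, results[0].bic)
    return results


def stage_scan(config: RunConfig, genome, pssms):
    """Scan all CDS promoter windows with the retained PSSMs (hit union)."""
    if isinstance(pssms, motif.PSSM):
        pssms = [pssms]
    windows = [
        genome_io.promoter_window(
            g, genome, config.promoter_upstream, config.promoter_downstream
        )
        for g in genome.cds()
    ]
    hits = []
    for pssm in pssms:
        hits.extend(
            motif.scan_promoters(pssm, windows, p_threshold=config.motif_p_threshold)
        )
    _write_table(
        motif.hits_to_frame(hits),
        os.path.join(config.output_dir, "motif_hits.tsv"), config, index=False,
    )
    motif.write_hits_gff3(
        hits, genome, os.path.join(config.output_dir, "motif_hits.gff3"),
        header=config.header(),
    )
    logger.info("scan: %d promoter hits (%d motifs) at p<=%g in %d windows",
                len(hits), len(pssms), config.motif_p_threshold, len(windows))
    return hits


def stage_de(config: RunConfig, counts, meta):
    params = diffexpr.DEParams(**config.de_params)
    results = diffexpr.run_de(counts, meta, params)
    patterns = diffexpr.classify_patterns(results, params)
    if config.apply_intermediate_filter:
        patterns = patterns.assign(
            selected=patterns.selected & patterns.intermediate_only
        )
    _write_table(results, os.path.join(config.output_dir, "de_results.tsv"),
                 config, index=False)
    _write_table(patterns, os.path.join(config.output_dir, "de_patterns.tsv"),
                 config, index=False)
    logger.info("de: %d genes selected by the DE-count pattern",
                int(patterns.selected.sum()))
    return results, patterns


def stage_integrate(config: RunConfig, genome, retained, candidates,
                    patterns, hits):
    gene_peaks, partners = integrate.assign_peaks_to_genes(
        [p for p in retained if p.location in ("intergenic", "tRNA-proximal")],
        genome, config.promoter_upstream, config.promoter_downstream,
    )
    operons = integrate.predict_operons(genome, config.operon_gap)
    evidence = integrate.build_lists(
        genome, gene_peaks, patterns, hits, operons, partners,
        p_threshold=config.motif_p_threshold,
    )
    bundle = integrate.report(evidence, genome, candidates, retained)
    _write_table(evidence, os.path.join(config.output_dir, "evidence.tsv"),
                 config, index=False)
    _write_table(bundle["table"], os.path.join(config.output_dir, "regulon.tsv"),
                 config, index=False)
    summary = dict(
        counts=bundle["counts"],
        counts_operon_collapsed=bundle["counts_operon_collapsed"],
        l1_consensus=bundle["l1_consensus"],
    )
    with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("integrate: L1=%d L2=%d L3=%d L4=%d",
                *(bundle["counts"][k] for k in ("L1", "L2", "L3", "L4")))
    return evidence, bundle


@dataclass
class RunResult:
    genome: object
    truth: object
    retained_peaks: list
    motifs: list
    hits: list
    de_results: pd.DataFrame
    patterns: pd.DataFrame
    evidence: pd.DataFrame
    bundle: dict


def run_all(config: RunConfig, simulate_inputs: bool | None = None) -> RunResult:
    """Execute the full pipeline; stage failures propagate with stage name."""
    os.makedirs(config.output_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.output_dir, "config.yaml"))
    truth = None
    stage = "inputs"
    try:
        if simulate_inputs or (simulate_inputs is None and not config.genome_fasta):
            stage = "simulate"
            genome, truth, tracks, counts, meta = stage_simulate(config)
        else:
            genome, tracks, counts, meta = load_inputs(config)
        stage = "callpeaks"
        retained, candidates = stage_callpeaks(config, genome, tracks)
        if config.skip_motif:
            motifs, hits = [], []
        else:
            stage = "discover"
            motifs = stage_discover(config, genome, retained)
            stage = "scan"
            hits = stage_scan(config, genome, [m.pssm for m in motifs])
        stage = "de"
        de_results, patterns = stage_de(config, counts, meta)
        stage = "integrate"
        evidence, bundle = stage_integrate(
            config, genome, retained, candidates, patterns, hits
        )
    except Exception:
        logger.exception("pipeline failed in stage %s", stage)
        raise
    return RunResult(
        genome=genome,
        truth=truth,
        retained_peaks=retained,
        motifs=motifs,
        hits=hits,
        de_results=de_results,
        patterns=patterns,
        evidence=evidence,
        bundle=bundle,
    )
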