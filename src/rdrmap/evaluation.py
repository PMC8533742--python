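"""Calibration and recovery measurements on synthetic studies.

Each function generates its own inputs from a seed, runs the relevant
pipeline stage(s) and returns the measured quantities, so validation runs
are reproducible end to end.  These are the quantitative checks behind
the package's stated operating characteristics: scanner exactness against
brute-force enumeration, motif recovery from planted sequences, peak-call
recall/precision and null behaviour, NB-test type-I error and power, and
whole-pipeline regulon recovery.
"""

from __future__ import annotations

import itertools
import time

import numpy as np
import pandas as pd

from . import diffexpr, pipeline
from .motif import (
    PSSM,
    discover_motifs,
    iupac_consensus,
    consensus_match_positions,
    pssm_distance,
    rdrm_fixture_pssm,
    score_pvalues,
)
from .simulate import SimulationConfig, simulate_chip, simulate_genome

PRINTED_CONSENSUS = "TATGYYHTTARCRKA"


def scanner_exactness(seed: int = 0, n_matrices: int = 20) -> dict:
    """Lattice p-values vs exhaustive enumeration of all 4^w words.

    For random PSSMs of width <= 8, every word's tail probability from the
    dynamic-programming convolution is compared against direct summation
    of background probabilities over all words scoring at least as high.
    Returns the maximum relative error over the whole suite.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_words = 0
    for _ in range(n_matrices):
        w = int(rng.integers(4, 9))
        mat = rng.dirichlet(np.full(4, 0.7), size=w)
        mat = np.clip(mat, 1e-3, None)
        mat /= mat.sum(axis=1, keepdims=True)
        background = rng.dirichlet(np.full(4, 5.0))
        dist = score_pvalues(PSSM(mat, background=background))
        words = np.array(list(itertools.product(range(4), repeat=w)))
        probs = background[words].prod(axis=1)
        ints = dist.int_scores[np.arange(w), words].sum(axis=1)
        order = np.argsort(-ints)
        sorted_ints = ints[order]
        cum = np.cumsum(probs[order])
        # tail prob per word = cumulative mass of all words with int >= own
        idx = np.searchsorted(-sorted_ints, -ints, side="right") - 1
        oracle = cum[idx]
        lattice = np.array([dist.pvalue(int(s)) for s in ints])
        rel = np.abs(lattice - oracle) / oracle
        worst = max(worst, float(rel.max()))
        n_words += len(words)
    return {"max_rel_error": worst, "n": n_words}


def motif_recovery(
    seed: int = 0,
    n_sequences: int = 40,
    n_planted: int = 35,
    length: int = 600,
    n_starts: int = 10,
) -> dict:
    """Recover a planted operator matrix by ZOOPS EM.

    Plants one sample from the operator-site fixture PSSM in
    ``n_planted`` of ``n_sequences`` random sequences, runs width-17 EM
    and reports the mean per-column total-variation distance between the
    recovered and planted matrices (aligned over strand and small phase
    shifts).
    """
    fixture, _ = rdrm_fixture_pssm()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequences = []
    for i in range(n_sequences):
        seq = "".join(bases[rng.integers(0, 4, length)])
        if i < n_planted:
            site = fixture.sample_site(rng)
            pos = int(rng.integers(0, length - fixture.width))
            seq = seq[:pos] + site + seq[pos + fixture.width :]
        sequences.append(seq)
    rng.shuffle(sequences)
    results = discover_motifs(
        sequences, width_range=(17, 17), mode="any", n_starts=n_starts,
        seed=seed,
    )
    tv = pssm_distance(results[0].pssm, fixture)
    return {"mean_column_tv": float(tv), "n": n_sequences}


def fixture_consensus() -> dict:
    """IUPAC consensus of the fixture PSSM vs the printed consensus.

    Positions match when the two degenerate codes' base sets intersect.
    """
    pssm, aligned = rdrm_fixture_pssm()
    consensus = iupac_consensus(pssm)
    matched = consensus_match_positions(consensus, PRINTED_CONSENSUS)
    return {
        "matched_positions": int(matched),
        "consensus": consensus,
        "n": len(PRINTED_CONSENSUS),
    }


def _call_consensus_peaks(genome, tracks, seed):
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        config = pipeline.RunConfig(output_dir=tmp, seed=seed)
        retained, _ = pipeline.stage_callpeaks(config, genome, tracks)
    return retained


def peak_calibration(seed: int = 0) -> dict:
    """Peak-caller recall/precision on a 200 kb planted genome, plus null.

    30 sites at 8x enrichment over a background of 5 reads/nt; the null
    genome re-uses the same layout with enrichment fold 1.
    """
    base = dict(
        n_genes=170,
        replicon_lengths=(200_000,),
        regulon_size=30,
        background_rate=5.0,
        chip_enrichment_fold=8.0,
    )
    config = SimulationConfig(seed=seed, **base)
    genome, truth = simulate_genome(config)
    tracks = simulate_chip(genome, truth, config)
    retained = _call_consensus_peaks(genome, tracks, seed)
    covered = 0
    for site in truth.planted_sites:
        mid = site.position + len(site.sequence) // 2
        covered += any(
            p.replicon_id == site.replicon_id and p.start <= mid < p.end
            for p in retained
        )
    with_site = 0
    for p in retained:
        with_site += any(
            s.replicon_id == p.replicon_id
            and p.start <= s.position + len(s.sequence) // 2 < p.end
            for s in truth.planted_sites
        )
    lengths = [p.length for p in retained]
    null_config = SimulationConfig(
        seed=seed, **{**base, "chip_enrichment_fold": 1.0}
    )
    n_genome, n_truth = simulate_genome(null_config)
    n_tracks = simulate_chip(n_genome, n_truth, null_config)
    null_peaks = _call_consensus_peaks(n_genome, n_tracks, seed)
    return {
        "recall": covered / len(truth.planted_sites),
        "precision": with_site / len(retained) if retained else float("nan"),
        "n_sites": len(truth.planted_sites),
        "n_peaks": len(retained),
        "min_length": int(min(lengths)) if lengths else 0,
        "max_length": int(max(lengths)) if lengths else 0,
        "null_peaks": len(null_peaks),
    }


def de_calibration(
    seed: int = 0,
    n_null: int = 2000,
    n_planted: int = 300,
    alpha: float = 0.1,
    base_mean: float = 200.0,
    fold: float = 8.0,
) -> dict:
    """Type-I error and power of the exact NB test at 3 vs 3 replicates."""
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        [
            {"sample": f"W37_t{t}_r{r}", "strain": "W37", "time": t,
             "replicate": r}
            for t in (1, 4)
            for r in (1, 2, 3)
        ]
    )
    size = 1.0 / alpha

    def nb(mean, shape):
        return rng.negative_binomial(size, size / (size + mean), size=shape)

    null = nb(base_mean, (n_null, 6))
    planted = np.hstack(
        [nb(base_mean, (n_planted, 3)), nb(base_mean * fold, (n_planted, 3))]
    )
    counts = pd.DataFrame(
        np.vstack([null, planted]),
        columns=meta["sample"],
        index=[f"g{i}" for i in range(n_null + n_planted)],
    )
    factors = diffexpr.size_factors(counts)
    disp = diffexpr.estimate_dispersion(counts, meta, factors)
    res = diffexpr.nb_test(counts, meta, "W37", 4, factors, disp)
    null_p = res.p_value.to_numpy()[:n_null]
    power = res.is_de.to_numpy()[n_null:].mean()
    return {
        "null_fraction_p01": float((null_p <= 0.01).mean()),
        "power": float(power),
        "n_null": n_null,
        "n_planted": n_planted,
    }


def end_to_end(seed: int = 0, output_dir: str | None = None) -> dict:
    """Whole-pipeline regulon recovery on the default synthetic study."""
    import tempfile

    t0 = time.time()
    with tempfile.TemporaryDirectory() as tmp:
        config = pipeline.RunConfig(output_dir=output_dir or tmp, seed=seed)
        result = pipeline.run_all(config, simulate_inputs=True)
    truth = result.truth
    l1 = set(result.evidence[result.evidence.list == "L1"].gene_id)
    regulon = set(truth.regulon_gene_ids)
    confounders = set(truth.confounder_gene_ids)
    tp = len(l1 & regulon)
    return {
        "l1_recall": tp / len(regulon),
        "l1_precision": tp / len(l1) if l1 else float("nan"),
        "confounder_rate": len(l1 & confounders) / len(confounders),
        "n_regulon": len(regulon),
        "n_l1": len(l1),
        "n_confounders": len(confounders),
        "runtime_s": time.time() - t0,
        "list_counts": result.bundle["counts"],
    }
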