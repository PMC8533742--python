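"""Time-course negative-binomial differential expression and pattern calls.

Each later time point is tested against the 1 h reference within a strain
using a two-group NB exact test (conditional on the two group sums, with
median-of-ratios size factors and method-of-moments dispersions).  A gene
is differentially expressed (DE) when its fold change is at least two-fold
and the raw p-value is at most 0.01.  The pattern classifier then selects
genes that are DE in few comparisons in the repressor-retaining control
strain (W37) but in many comparisons in the depletion strain (D37) — the
signature of de-repression during the time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

TIMES = (1, 4, 6, 8, 16, 24)
STRAINS = ("W37", "D37")


@dataclass
class DEParams:
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    reference_time: int = 1
    dispersion_floor: float = 0.01
    # "le2": selected iff DE-count(W37) <= 2 and DE-count(D37) > 3 (main rule)
    # "lt2": legend variant, DE-count(W37) < 2
    pattern_rule: str = "le2"
    intermediate_times: tuple[int, ...] = (6, 8, 16)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over genes of count_gj / geometric-mean_g, using only
    genes with no zero count (the geometric reference is undefined there).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene without zeros; cannot compute size factors")
    logs = np.log(mat[nonzero])
    log_geo = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_geo, axis=0)
    # rescale to geometric mean 1 so normalization is exactly idempotent
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None):
    factors = size_factors(counts) if factors is None else factors
    return counts / factors


def estimate_dispersion(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: pd.Series | None = None,
    floor: float = 0.01,
    trend_window: int | None = None,
) -> pd.Series:
    """Per-gene NB dispersion alpha (variance = mu + alpha * mu^2).

    Method-of-moments pooled across (strain, time) conditions on
    normalized counts (per-condition centering absorbs fold changes;
    pooling with df weights keeps the estimate stable at 3 replicates),
    blended with a monotone (non-increasing in mean) rolling-median trend
    over genes ranked by mean expression:
    alpha = max(alpha_hat, trend, floor) — the conservative "maximum"
    sharing mode of classic NB differential-expression analyses.
    """
    norm = normalized_counts(counts, factors)
    conditions = meta.groupby(["strain", "time"]).groups
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for _, samples in conditions.items():
        sub = norm[meta.loc[samples, "sample"]]
        if sub.shape[1] < 2:
            continue
        df = sub.shape[1] - 1
        mean = sub.mean(axis=1).to_numpy()
        var = sub.var(axis=1, ddof=1).to_numpy()
        num += (var - mean) * df
        den += mean**2 * df
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = np.where(den > 0, num / den, 0.0)
    per_gene = np.clip(per_gene, 0, None)
    # monotone mean-dispersion trend
    overall = norm.mean(axis=1).to_numpy()
    order = np.argsort(overall)
    n = per_gene.size
    window = trend_window or max(11, n // 20)
    rolled = (
        pd.Series(per_gene[order]).rolling(window, center=True, min_periods=1).median()
    ).to_numpy()
    # enforce non-increasing trend in mean via a decreasing running envelope
    trend_sorted = np.minimum.accumulate(np.maximum.accumulate(rolled[::-1])[::-1])
    trend = np.empty(n)
    trend[order] = trend_sorted
    alpha = np.maximum.reduce([per_gene, trend, np.full(n, floor)])
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _group_nb_params(q: float, s_sum: float, s_sq: float, alpha: float):
    """Mean and size of the NB model for a sum of replicate counts.

    mean = q * sum(s_j); var = sum(q s_j + alpha (q s_j)^2).
    """
    mu = q * s_sum
    var = mu + alpha * q**2 * s_sq
    if var <= mu:
        size = 1e8  # effectively Poisson
    else:
        size = mu**2 / (var - mu)
    return mu, size


def _exact_test(ka: int, kb: int, mu_a, size_a, mu_b, size_b) -> float:
    """Two-sided exact NB test conditional on the total ka + kb.

    Sums the probabilities of all splits (a, k - a) that are no more likely
    than the observed split, normalised over all splits.
    """
    k = ka + kb
    if k == 0:
        return 1.0
    if k <= 5_000:
        a = np.arange(0, k + 1)
    else:
        # prune the support to the null mode and the observed split; mass
        # outside +-20 sd of both is negligible at any reported precision
        sd = np.sqrt(mu_a + mu_a**2 / size_a) + np.sqrt(mu_b + mu_b**2 / size_b)
        centers = (min(mu_a, k - mu_b, ka), max(mu_a, k - mu_b, ka))
        ranges = [
            np.arange(
                max(0, int(c - 20 * sd - 10)), min(k, int(c + 20 * sd + 10)) + 1
            )
            for c in centers
        ]
        a = np.unique(np.concatenate(ranges))
    logp = stats.nbinom.logpmf(a, size_a, size_a / (size_a + mu_a)) + stats.nbinom.logpmf(
        k - a, size_b, size_b / (size_b + mu_b)
    )
    log_obs = stats.nbinom.logpmf(
        ka, size_a, size_a / (size_a + mu_a)
    ) + stats.nbinom.logpmf(kb, size_b, size_b / (size_b + mu_b))
    total = logsumexp(logp)
    keep = logp <= log_obs + 1e-12
    if not keep.any():
        return 1.0
    return float(min(np.exp(logsumexp(logp[keep]) - total), 1.0))


def nb_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    strain: str,
    time: int,
    factors: pd.Series,
    dispersions: pd.Series,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Exact NB test of one (strain, time) against the 1 h reference.

    Returns a per-gene frame with log2fc, p_value, is_de and direction.
    The fold change is computed from normalized group means with a
    pseudo-mean of 0.5; is_de requires both |FC| >= fc_threshold and
    p <= p_threshold.
    """
    params = params or DEParams()
    ref = meta[(meta.strain == strain) & (meta.time == params.reference_time)]
    grp = meta[(meta.strain == strain) & (meta.time == time)]
    if ref.empty or grp.empty:
        raise ValueError(f"missing samples for {strain} t={time}")
    cols_a, cols_b = list(ref["sample"]), list(grp["sample"])
    sf_a, sf_b = factors[cols_a].to_numpy(), factors[cols_b].to_numpy()
    mat_a = counts[cols_a].to_numpy()
    mat_b = counts[cols_b].to_numpy()
    ka, kb = mat_a.sum(axis=1), mat_b.sum(axis=1)
    q = (ka + kb) / (sf_a.sum() + sf_b.sum())
    mean_a = (mat_a / sf_a).mean(axis=1)
    mean_b = (mat_b / sf_b).mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    pvals = np.ones(counts.shape[0])
    alphas = dispersions.to_numpy()
    for i in range(counts.shape[0]):
        if ka[i] + kb[i] == 0:
            pvals[i] = 1.0
            continue
        mu_a, size_a = _group_nb_params(q[i], sf_a.sum(), (sf_a**2).sum(), alphas[i])
        mu_b, size_b = _group_nb_params(q[i], sf_b.sum(), (sf_b**2).sum(), alphas[i])
        pvals[i] = _exact_test(int(ka[i]), int(kb[i]), mu_a, size_a, mu_b, size_b)
    is_de = (pvals <= params.p_threshold) & (
        np.abs(log2fc) >= np.log2(params.fc_threshold)
    )
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))
    zero = (ka + kb) == 0
    log2fc = np.where(zero, 0.0, log2fc)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "strain": strain,
            "time": time,
            "log2fc": log2fc,
            "p_value": pvals,
            "is_de": is_de,
            "direction": direction,
        }
    ).set_index("gene_id", drop=False)


def run_de(
    counts: pd.DataFrame, meta: pd.DataFrame, params: DEParams | None = None
) -> pd.DataFrame:
    """All (strain, time vs 1 h) comparisons, concatenated."""
    params = params or DEParams()
    factors = size_factors(counts)
    dispersions = estimate_dispersion(
        counts, meta, factors, floor=params.dispersion_floor
    )
    frames = []
    for strain in sorted(meta.strain.unique()):
        for time in sorted(meta.time.unique()):
            if time == params.reference_time:
                continue
            frames.append(
                nb_test(counts, meta, strain, int(time), factors, dispersions, params)
            )
    return pd.concat(frames, ignore_index=True)


def classify_patterns(
    results: pd.DataFrame,
    params: DEParams | None = None,
    expected_times: list[int] | None = None,
) -> pd.DataFrame:
    """Per-gene DE-count pattern across the time course.

    selected <=> DE-count in W37 at most 2 (or < 2 under the legend-variant
    rule) AND DE-count in D37 greater than 3.  ``intermediate_only`` flags
    genes whose D37 DE calls are confined to the intermediate time points;
    it is reported, not applied.
    """
    params = params or DEParams()
    strains = sorted(results.strain.unique()) or list(STRAINS)
    times = expected_times or [t for t in TIMES if t != params.reference_time]
    expected = {(s, t) for s in strains for t in times}
    seen = set(zip(results.strain, results.time))
    if expected - seen:
        raise ValueError(f"missing comparisons: {sorted(expected - seen)}")
    de = results[results.is_de]
    genes = results.gene_id.unique()
    count_w = de[de.strain == "W37"].groupby("gene_id").size()
    count_d = de[de.strain == "D37"].groupby("gene_id").size()
    d37 = de[de.strain == "D37"]
    inter = set(params.intermediate_times)
    rows = []
    d37_by_gene = {g: sub for g, sub in d37.groupby("gene_id")}
    for g in genes:
        cw = int(count_w.get(g, 0))
        cd = int(count_d.get(g, 0))
        if params.pattern_rule == "le2":
            selected = cw <= 2 and cd > 3
        elif params.pattern_rule == "lt2":
            selected = cw < 2 and cd > 3
        else:
            raise ValueError(f"unknown pattern rule {params.pattern_rule}")
        sub = d37_by_gene.get(g)
        if sub is None or len(sub) == 0:
            intermediate_only = False
            direction = "none"
        else:
            intermediate_only = set(sub.time).issubset(inter)
            dirs = set(sub.direction)
            direction = dirs.pop() if len(dirs) == 1 else "mixed"
        rows.append(
            {
                "gene_id": g,
                "de_count_W37": cw,
                "de_count_D37": cd,
                "selected": selected,
                "intermediate_only": intermediate_only,
                "direction_in_D37": direction,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id", drop=False)
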