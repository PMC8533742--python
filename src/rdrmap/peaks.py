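"""Sliding-window ChIP peak detection for small genomes.

The caller mirrors the bPeaks strategy for compact bacterial genomes:
fixed windows slid at a fixed step are flagged when (i) the IP signal
exceeds a multiple of its genome-wide mean, (ii) the log2 IP/control
ratio exceeds a threshold, and (iii) the window clears a coverage
quantile; flagged windows are merged into peaks.  Each IP replicate is
called against both the Input and the Mock control, and a region is
retained only when both comparisons support it in a majority of
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, intergenic_regions


@dataclass
class CoverageTrack:
    """Per-base coverage for one sample across all replicons."""

    sample_id: str
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        for rep, arr in self.data.items():
            if np.any(arr < 0):
                raise ValueError(f"{self.sample_id}/{rep}: negative coverage")

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.sample_id, {k: v * factor for k, v in self.data.items()}
        )


@dataclass
class PeakParams:
    """Thresholds for window-level significance and peak assembly."""

    window: int = 150
    step: int = 50
    ip_coeff: float = 2.0       # T1: multiple of the genome-wide IP mean
    ratio_log2: float = 1.0     # T2: log2((ip+eps)/(control+eps)) threshold
    coverage_quantile: float = 0.5
    merge_gap: int = 50
    min_replicates: int = 2
    # pseudo-coverage in the log-ratio, in units of the genome-wide IP mean
    # (relative units keep peak calls invariant under global rescaling)
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("require window >= step > 0")
        if self.ip_coeff <= 0:
            raise ValueError("ip_coeff must be > 0")
        if not 0 <= self.coverage_quantile < 1:
            raise ValueError("coverage_quantile must be in [0, 1)")


@dataclass
class Peak:
    """A called enriched interval, half-open on its replicon."""

    replicon_id: str
    start: int
    end: int
    summit: int
    mean_ip: float
    mean_control: float
    mean_mock: float = float("nan")
    location: str = "unclassified"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_tracks(tracks: list[CoverageTrack]) -> list[CoverageTrack]:
    """Scale each track by (mean library total / its total)."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to normalize")
    totals = [t.total for t in tracks]
    if any(tot == 0 for tot in totals):
        raise ValueError("zero-total track cannot be normalized")
    target = float(np.mean(totals))
    return [t.scaled(target / tot) for t, tot in zip(tracks, totals)]


def _window_starts(length: int, params: PeakParams) -> np.ndarray:
    if length < params.window:
        return np.array([], dtype=int)
    return np.arange(0, length - params.window + 1, params.step)


def _window_means(arr: np.ndarray, params: PeakParams) -> np.ndarray:
    """Mean coverage of each sliding window."""
    starts = _window_starts(arr.size, params)
    if starts.size == 0:
        return np.array([])
    csum = np.concatenate([[0.0], np.cumsum(arr)])
    return (csum[starts + params.window] - csum[starts]) / params.window


def call_peaks_one(
    ip: CoverageTrack, control: CoverageTrack, params: PeakParams
) -> list[Peak]:
    """Call peaks for one IP track against one control track.

    A window is significant iff its IP mean is at least ``ip_coeff`` times
    the genome-wide IP mean, its pseudo-count log2 IP/control ratio is at
    least ``ratio_log2``, and its IP mean clears the
    ``coverage_quantile``-quantile of all windowed IP means.  Overlapping
    or near-adjacent (gap <= merge_gap) significant windows are merged;
    the summit is the leftmost argmax of IP coverage within the peak.
    """
    genome_mean = ip.total / sum(arr.size for arr in ip.data.values())
    all_means = np.concatenate(
        [_window_means(ip.data[rep], params) for rep in ip.data]
    )
    quantile = float(np.quantile(all_means, params.coverage_quantile))
    eps = params.epsilon * genome_mean
    peaks: list[Peak] = []
    for rep, arr in ip.data.items():
        starts = _window_starts(arr.size, params)
        if starts.size == 0:
            continue
        mean_ip = _window_means(arr, params)
        mean_ctl = _window_means(control.data[rep], params)
        ratio = np.log2((mean_ip + eps) / (mean_ctl + eps))
        sig = (
            (mean_ip >= params.ip_coeff * genome_mean)
            & (ratio >= params.ratio_log2)
            & (mean_ip >= quantile)
        )
        for s, e in _merge_intervals(
            [(int(st), int(st) + params.window) for st in starts[sig]],
            params.merge_gap,
        ):
            summit = s + int(np.argmax(arr[s:e]))
            peaks.append(
                Peak(
                    replicon_id=rep,
                    start=s,
                    end=e,
                    summit=summit,
                    mean_ip=float(arr[s:e].mean()),
                    mean_control=float(control.data[rep][s:e].mean()),
                )
            )
    return peaks


def _merge_intervals(
    intervals: list[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    """Merge sorted-or-not half-open intervals closer than ``gap``."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def retain_consensus_peaks(
    per_replicate_vs_input: list[list[Peak]],
    per_replicate_vs_mock: list[list[Peak]],
    params: PeakParams,
    mean_ip: CoverageTrack | None = None,
) -> list[Peak]:
    """Keep regions supported by both control comparisons in >= k replicates.

    Within each replicate, every vs-Input peak that overlaps (>= 1 bp) a
    vs-Mock peak contributes the union span of the pair; a base is retained
    when such support exists in at least ``min_replicates`` replicates.
    Retained bases are assembled into peaks (merge_gap applies) and regions
    shorter than one window are discarded.  Scores are means over the
    supporting per-replicate peaks; the summit is recomputed from the mean
    IP coverage when provided, else from supporting summits.
    """
    if len(per_replicate_vs_input) != len(per_replicate_vs_mock):
        raise ValueError("replicate lists must be parallel")
    support: dict[str, list[list[tuple[int, int]]]] = {}
    n_rep = len(per_replicate_vs_input)
    for r, (vs_in, vs_mock) in enumerate(
        zip(per_replicate_vs_input, per_replicate_vs_mock)
    ):
        for p_in in vs_in:
            for p_mock in vs_mock:
                if p_mock.replicon_id != p_in.replicon_id:
                    continue
                if p_in.start < p_mock.end and p_mock.start < p_in.end:
                    span = (min(p_in.start, p_mock.start), max(p_in.end, p_mock.end))
                    support.setdefault(p_in.replicon_id, [[] for _ in range(n_rep)])[
                        r
                    ].append(span)
    retained: list[Peak] = []
    for rep_id, by_rep in support.items():
        length = 1 + max(e for spans in by_rep for _, e in spans)
        depth = np.zeros(length, dtype=int)
        for spans in by_rep:
            for s, e in _merge_intervals(spans, 0):
                depth[s:e] += 1
        mask = depth >= params.min_replicates
        regions = _mask_to_intervals(mask)
        regions = _merge_intervals(regions, params.merge_gap)
        for s, e in regions:
            if e - s < params.window:
                continue
            sup = [
                p
                for lst in (per_replicate_vs_input, per_replicate_vs_mock)
                for rep_peaks in lst
                for p in rep_peaks
                if p.replicon_id == rep_id and p.start < e and s < p.end
            ]
            sup_in = [
                p
                for rep_peaks in per_replicate_vs_input
                for p in rep_peaks
                if p.replicon_id == rep_id and p.start < e and s < p.end
            ]
            sup_mock = [
                p
                for rep_peaks in per_replicate_vs_mock
                for p in rep_peaks
                if p.replicon_id == rep_id and p.start < e and s < p.end
            ]
            if mean_ip is not None:
                arr = mean_ip.data[rep_id]
                summit = s + int(np.argmax(arr[s:e]))
            else:
                summit = int(np.median([p.summit for p in sup]))
                summit = min(max(summit, s), e - 1)
            retained.append(
                Peak(
                    replicon_id=rep_id,
                    start=s,
                    end=e,
                    summit=summit,
                    mean_ip=float(np.mean([p.mean_ip for p in sup])),
                    mean_control=float(np.mean([p.mean_control for p in sup_in]))
                    if sup_in
                    else float("nan"),
                    mean_mock=float(np.mean([p.mean_control for p in sup_mock]))
                    if sup_mock
                    else float("nan"),
                )
            )
    retained.sort(key=lambda p: (p.replicon_id, p.start))
    for i, p in enumerate(retained):
        p.name = f"peak_{i + 1}"
    return retained


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    diff = np.diff(mask.astype(int))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def classify_location(
    peak: Peak,
    genome: GenomeAnnotation,
    trna_margin: int = 100,
    _intergenic: list[tuple[str, int, int]] | None = None,
) -> str:
    """Classify a peak by its summit: intergenic, tRNA-proximal or intragenic."""
    regions = intergenic_regions(genome) if _intergenic is None else _intergenic
    for rep, s, e in regions:
        if rep == peak.replicon_id and s <= peak.summit < e:
            return "intergenic"
    for g in genome.genes:
        if g.kind == "tRNA" and g.replicon_id == peak.replicon_id:
            if g.start - trna_margin <= peak.summit < g.end + trna_margin:
                return "tRNA-proximal"
    return "intragenic"


def classify_peaks(
    peaks: list[Peak], genome: GenomeAnnotation, trna_margin: int = 100
) -> list[Peak]:
    regions = intergenic_regions(genome)
    return [
        replace(p, location=classify_location(p, genome, trna_margin, regions))
        for p in peaks
    ]


def peak_sequences(peaks: list[Peak], genome: GenomeAnnotation) -> list[str]:
    return [
        genome.replicons[p.replicon_id].sequence[p.start : p.end] for p in peaks
    ]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": p.replicon_id,
                "start": p.start,
                "end": p.end,
                "name": p.name,
                "summit": p.summit,
                "mean_ip": p.mean_ip,
                "mean_input": p.mean_control,
                "mean_mock": p.mean_mock,
                "location": p.location,
            }
            for p in peaks
        ],
        columns=[
            "replicon", "start", "end", "name", "summit",
            "mean_ip", "mean_input", "mean_mock", "location",
        ],
    )


# ---------------------------------------------------------------------------
# Coverage I/O


def write_bedgraph(track: CoverageTrack, path: str, header: str = "") -> None:
    """Write per-base coverage as bedGraph (runs of equal value collapsed)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rep, arr in track.data.items():
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{rep}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path: str, sample_id: str, lengths: dict[str, int]) -> CoverageTrack:
    """Read a bedGraph into a dense per-base track with known replicon lengths."""
    data = {rep: np.zeros(n) for rep, n in lengths.items()}
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["replicon", "start", "end", "value"], dtype={"replicon": str},
    )
    for row in df.itertuples(index=False):
        data[row.replicon][row.start : row.end] = row.value
    return CoverageTrack(sample_id, data)


def pileup_fragments(
    path: str, sample_id: str, lengths: dict[str, int]
) -> CoverageTrack:
    """Pile a fragment BED file into per-base coverage."""
    data = {rep: np.zeros(n) for rep, n in lengths.items()}
    df = pd.read_csv(
        path, sep="\t", comment="#", usecols=[0, 1, 2],
        names=["replicon", "start", "end"], dtype={"replicon": str},
    )
    for row in df.itertuples(index=False):
        arr = data[row.replicon]
        arr[max(row.start, 0) : min(row.end, arr.size)] += 1
    return CoverageTrack(sample_id, data)


def write_peaks_bed(peaks: list[Peak], path: str, header: str = "") -> None:
    """BED6 + summit column (narrowPeak-style relative summit offset)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for p in peaks:
            fh.write(
                f"{p.replicon_id}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{p.mean_ip:.3f}\t.\t{p.summit - p.start}\n"
            )
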