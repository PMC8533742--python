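"""Peak caller: window criteria, consensus retention, classification."""

import numpy as np
import pytest

from rdrmap.genome import Gene, GenomeAnnotation, Replicon
from rdrmap.peaks import (
    CoverageTrack,
    Peak,
    PeakParams,
    call_peaks_one,
    classify_location,
    classify_peaks,
    normalize_tracks,
    retain_consensus_peaks,
)


def flat_track(name, value, length=10_000):
    return CoverageTrack(name, {"c": np.full(length, float(value))})


def bumped_track(name, value, bumps, length=10_000, rng=None):
    arr = np.full(length, float(value))
    if rng is not None:
        arr = rng.poisson(value, length).astype(float)
    for center, height, half in bumps:
        x = np.arange(length)
        arr += height * np.clip(1 - np.abs(x - center) / half, 0, None)
    return CoverageTrack(name, {"c": arr})


class TestNormalize:
    def test_identical_tracks_unchanged(self):
        a, b = flat_track("a", 5), flat_track("b", 5)
        na, nb = normalize_tracks([a, b])
        assert np.allclose(na.data["c"], a.data["c"])
        assert np.allclose(nb.data["c"], b.data["c"])

    def test_doubled_track_matches_after_normalization(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5, 5000).astype(float)
        a = CoverageTrack("a", {"c": base})
        b = CoverageTrack("b", {"c": 2 * base})
        na, nb = normalize_tracks([a, b])
        assert np.allclose(na.data["c"], nb.data["c"])

    def test_normalized_totals_are_equal(self):
        rng = np.random.default_rng(1)
        tracks = [
            CoverageTrack(f"t{i}", {"c": rng.poisson(3 + i, 4000).astype(float)})
            for i in range(4)
        ]
        normed = normalize_tracks(tracks)
        totals = [t.total for t in normed]
        assert np.allclose(totals, totals[0])

    def test_zero_total_track_is_an_error(self):
        with pytest.raises(ValueError, match="zero-total"):
            normalize_tracks([flat_track("a", 0), flat_track("b", 5)])


class TestCallPeaksOne:
    def test_flat_equal_tracks_give_no_peaks(self):
        ip, ctl = flat_track("ip", 5), flat_track("ctl", 5)
        assert call_peaks_one(ip, ctl, PeakParams()) == []

    def test_single_planted_bump_gives_one_covering_peak(self):
        rng = np.random.default_rng(2)
        ip = bumped_track("ip", 5, [(5000, 35, 200)], rng=rng)
        ctl = bumped_track("ctl", 5, [], rng=rng)
        peaks = call_peaks_one(ip, ctl, PeakParams())
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start <= 5000 <= p.end
        assert 150 <= p.length <= 1400
        assert abs(p.summit - 5000) < 150

    def test_window_calls_match_brute_force_oracle(self):
        """Re-derive every window's three criteria independently."""
        rng = np.random.default_rng(3)
        params = PeakParams()
        ip = bumped_track("ip", 5, [(2000, 30, 200), (7000, 40, 150)], rng=rng)
        ctl = bumped_track("ctl", 5, [], rng=rng)
        arr, ctl_arr = ip.data["c"], ctl.data["c"]
        genome_mean = arr.mean()
        starts = np.arange(0, arr.size - params.window + 1, params.step)
        means = np.array([arr[s : s + params.window].mean() for s in starts])
        ctl_means = np.array(
            [ctl_arr[s : s + params.window].mean() for s in starts]
        )
        q = np.quantile(means, params.coverage_quantile)
        eps = params.epsilon * genome_mean
        sig = (
            (means >= params.ip_coeff * genome_mean)
            & (np.log2((means + eps) / (ctl_means + eps)) >= params.ratio_log2)
            & (means >= q)
        )
        expected = np.zeros(arr.size, dtype=bool)
        for s in starts[sig]:
            expected[s : s + params.window] = True
        called = np.zeros(arr.size, dtype=bool)
        for p in call_peaks_one(ip, ctl, params):
            called[p.start : p.end] = True
        # merging can only bridge gaps <= merge_gap; compare window cover
        assert np.array_equal(
            np.flatnonzero(expected), np.flatnonzero(called & expected)
        )
        bridged = called & ~expected
        assert bridged.sum() <= sig.sum() * params.merge_gap

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        ip = bumped_track("ip", 5, [(5000, 35, 200)], rng=rng)
        ctl = bumped_track("ctl", 5, [], rng=rng)
        base = call_peaks_one(ip, ctl, PeakParams())
        scaled = call_peaks_one(
            ip.scaled(7.3), ctl.scaled(7.3), PeakParams()
        )
        assert [(p.start, p.end, p.summit) for p in base] == [
            (p.start, p.end, p.summit) for p in scaled
        ]

    @pytest.mark.parametrize("param,stricter", [("ip_coeff", 3.0),
                                                ("ratio_log2", 2.0)])
    def test_raising_thresholds_never_adds_peaks(self, param, stricter):
        rng = np.random.default_rng(5)
        ip = bumped_track("ip", 5, [(3000, 20, 200), (7000, 45, 200)], rng=rng)
        ctl = bumped_track("ctl", 5, [], rng=rng)
        loose = call_peaks_one(ip, ctl, PeakParams())
        strict = call_peaks_one(ip, ctl, PeakParams(**{param: stricter}))
        loose_cover = np.zeros(10_000, dtype=bool)
        for p in loose:
            loose_cover[p.start : p.end] = True
        for p in strict:
            assert loose_cover[p.start : p.end].all()


def mkpeak(s, e, rep="c"):
    return Peak(rep, s, e, summit=(s + e) // 2, mean_ip=10.0, mean_control=2.0)


class TestRetainConsensus:
    PARAMS = PeakParams(min_replicates=2)

    def test_peak_in_all_lists_is_retained(self):
        vs_in = [[mkpeak(1000, 1400)] for _ in range(3)]
        vs_mock = [[mkpeak(1050, 1450)] for _ in range(3)]
        out = retain_consensus_peaks(vs_in, vs_mock, self.PARAMS)
        assert len(out) == 1
        assert out[0].start <= 1050 and out[0].end >= 1400

    def test_peak_missing_from_mock_comparison_is_dropped(self):
        vs_in = [[mkpeak(1000, 1400)] for _ in range(3)]
        vs_mock = [[] for _ in range(3)]
        assert retain_consensus_peaks(vs_in, vs_mock, self.PARAMS) == []

    def test_single_replicate_support_is_dropped(self):
        vs_in = [[mkpeak(1000, 1400)], [], []]
        vs_mock = [[mkpeak(1000, 1400)], [], []]
        assert retain_consensus_peaks(vs_in, vs_mock, self.PARAMS) == []

    def test_randomized_sets_match_brute_force_support_oracle(self):
        rng = np.random.default_rng(6)
        length = 30_000
        params = PeakParams(min_replicates=2, merge_gap=0)

        def random_peaks():
            out = []
            for _ in range(rng.integers(2, 6)):
                s = int(rng.integers(0, length - 1500))
                out.append(mkpeak(s, s + int(rng.integers(150, 800))))
            return out

        for _ in range(10):
            vs_in = [random_peaks() for _ in range(3)]
            vs_mock = [random_peaks() for _ in range(3)]
            depth = np.zeros(length, dtype=int)
            for r in range(3):
                cover = np.zeros(length, dtype=bool)
                for a in vs_in[r]:
                    for b in vs_mock[r]:
                        if a.start < b.end and b.start < a.end:
                            cover[min(a.start, b.start) : max(a.end, b.end)] = True
                depth += cover
            expected = depth >= 2
            got = np.zeros(length, dtype=bool)
            for p in retain_consensus_peaks(vs_in, vs_mock, params):
                got[p.start : p.end] = True
            # regions shorter than one window are discarded by design
            diff = expected & ~got
            segments = np.split(
                np.flatnonzero(diff), np.where(np.diff(np.flatnonzero(diff)) > 1)[0] + 1
            ) if diff.any() else []
            for seg in segments:
                assert len(seg) < params.window
            assert not (got & ~expected).any()


class TestClassifyLocation:
    def test_summit_inside_cds_is_intragenic(self, toy_genome):
        p = Peak("chr1", 1400, 1700, 1500, 10, 2)
        assert classify_location(p, toy_genome) == "intragenic"

    def test_summit_between_divergent_genes_is_intergenic(self, toy_genome):
        p = Peak("chr1", 4400, 4600, 4500, 10, 2)
        assert classify_location(p, toy_genome) == "intergenic"

    def test_summit_near_trna_is_trna_proximal(self, toy_genome):
        # the tRNA gene spans [7000, 7080); a summit 90 nt away qualifies
        p = Peak("chr1", 6800, 7010, 6950, 10, 2)
        # 6950 is intergenic AND within 100 of the tRNA: intergenic wins
        assert classify_location(p, toy_genome) == "intergenic"

    def test_classification_matches_interval_membership_oracle(self, toy_genome):
        from rdrmap.genome import intergenic_regions

        rng = np.random.default_rng(7)
        inter = intergenic_regions(toy_genome)
        peaks = []
        for _ in range(40):
            s = int(rng.integers(0, 9_500))
            peaks.append(Peak("chr1", s, s + 300, s + 150, 10, 2))
        for p, cp in zip(peaks, classify_peaks(peaks, toy_genome)):
            in_inter = any(
                r == "chr1" and s <= p.summit < e for r, s, e in inter
            )
            near_trna = any(
                g.kind == "tRNA"
                and g.replicon_id == "chr1"
                and g.start - 100 <= p.summit < g.end + 100
                for g in toy_genome.genes
            )
            expected = (
                "intergenic" if in_inter
                else ("tRNA-proximal" if near_trna else "intragenic")
            )
            assert cp.location == expected
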