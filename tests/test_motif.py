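"""PSSM estimation, exact p-values, scanning and ZOOPS EM discovery."""

import itertools

import numpy as np
import pytest

from rdrmap.genome import PromoterWindow, revcomp
from rdrmap.motif import (
    PSSM,
    align_sites,
    background_from_sequences,
    consensus_match_positions,
    discover_motifs,
    iupac_consensus,
    load_rdrm_sites,
    pssm_distance,
    pssm_from_sites,
    rdrm_fixture_pssm,
    read_meme,
    scan_promoters,
    score_pvalues,
    write_meme,
)

PRINTED_CONSENSUS = "TATGYYHTTARCRKA"


def window(seq, gene_id="g", first_offset=-500):
    return PromoterWindow(
        gene_id=gene_id,
        sequence=seq,
        first_offset=first_offset,
        replicon_id="c",
        genomic_start=0,
        genomic_end=len(seq),
        strand="+",
    )


class TestPssmFromSites:
    def test_one_of_each_base_gives_uniform_column(self):
        for pc in (0.1, 0.25, 1.0):
            pssm = pssm_from_sites(["A", "C", "G", "T"], pseudocount=pc)
            assert np.allclose(pssm.matrix[0], 0.25)

    def test_single_site_pseudocount_formula(self):
        pssm = pssm_from_sites(["ACGT"], pseudocount=0.25)
        assert np.isclose(pssm.matrix.max(), 1.25 / 2.0)

    def test_zero_pseudocount_disallowed(self):
        with pytest.raises(ValueError):
            pssm_from_sites(["ACGT"], pseudocount=0.0)

    def test_empty_site_list_is_an_error(self):
        with pytest.raises(ValueError):
            pssm_from_sites([])


class TestFixture:
    def test_fixture_has_38_sites_of_printed_lengths(self):
        sites = load_rdrm_sites()
        assert len(sites) == 38
        assert set(sites["site"].str.len()) <= {18, 19, 20}

    def test_fixture_consensus_is_compatible_with_printed_consensus(self):
        pssm, aligned = rdrm_fixture_pssm()
        assert all(len(s) == 17 for s in aligned)
        consensus = iupac_consensus(pssm)
        assert consensus_match_positions(consensus, PRINTED_CONSENSUS) >= 12


class TestScorePvalues:
    def test_uniform_pssm_scores_zero_with_p_one(self):
        pssm = PSSM(np.full((5, 4), 0.25))
        dist = score_pvalues(pssm)
        assert dist.pvalue_of_word("ACGTA") == pytest.approx(1.0)
        assert dist.bits(dist.int_score("ACGTA")) == pytest.approx(0.0, abs=1e-9)

    def test_tail_is_monotone_with_p_one_at_minimum(self):
        rng = np.random.default_rng(0)
        mat = rng.dirichlet(np.full(4, 0.8), size=6)
        dist = score_pvalues(PSSM(np.clip(mat, 1e-3, None) /
                                  np.clip(mat, 1e-3, None).sum(1, keepdims=True)))
        assert dist.pvalue(0) == pytest.approx(1.0)
        assert np.all(np.diff(dist.tail) <= 1e-12)

    def test_lattice_matches_word_enumeration_for_small_widths(self):
        """Brute-force oracle: sum background probabilities over all 4^w words."""
        rng = np.random.default_rng(1)
        for _ in range(3):
            w = int(rng.integers(4, 8))
            mat = rng.dirichlet(np.full(4, 0.7), size=w)
            mat = np.clip(mat, 1e-3, None)
            mat /= mat.sum(1, keepdims=True)
            bg = rng.dirichlet(np.full(4, 5.0))
            dist = score_pvalues(PSSM(mat, background=bg))
            words = np.array(list(itertools.product(range(4), repeat=w)))
            probs = bg[words].prod(axis=1)
            ints = dist.int_scores[np.arange(w), words].sum(axis=1)
            for idx in rng.choice(len(words), 50, replace=False):
                oracle = probs[ints >= ints[idx]].sum()
                assert dist.pvalue(int(ints[idx])) == pytest.approx(
                    oracle, rel=1e-9
                )

    def test_lattice_converges_to_exact_enumeration_with_bins(self):
        """Refining the lattice drives p-values to the exact-score truth."""
        rng = np.random.default_rng(2)
        w = 6
        mat = rng.dirichlet(np.full(4, 0.7), size=w)
        mat = np.clip(mat, 1e-3, None)
        mat /= mat.sum(1, keepdims=True)
        bg = rng.dirichlet(np.full(4, 5.0))
        pssm = PSSM(mat, background=bg)
        words = np.array(list(itertools.product(range(4), repeat=w)))
        probs = bg[words].prod(axis=1)
        scores = pssm.log_odds()[np.arange(w), words].sum(axis=1)
        order = np.argsort(-scores)
        exact = np.empty(len(words))
        exact[order] = np.cumsum(probs[order])
        med = {}
        for n_bins in (1_000, 10_000):
            dist = score_pvalues(pssm, n_bins=n_bins)
            ints = dist.int_scores[np.arange(w), words].sum(axis=1)
            lat = np.array([dist.pvalue(int(s)) for s in ints])
            med[n_bins] = np.median(np.abs(lat - exact) / exact)
        assert med[10_000] <= med[1_000]
        assert med[10_000] <= 1e-6


class TestScanPromoters:
    def test_planted_best_word_is_hit_at_its_offset(self):
        pssm, aligned = rdrm_fixture_pssm()
        best = "".join("ACGT"[int(c)] for c in pssm.matrix.argmax(axis=1))
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        seq = seq[:150] + best + seq[150 + 17 :]
        hits = scan_promoters(pssm, [window(seq)], background=None)
        assert any(h.offset == -500 + 150 and h.p_value <= 1e-4 for h in hits)

    def test_all_n_window_has_no_hits(self):
        pssm, _ = rdrm_fixture_pssm()
        assert scan_promoters(pssm, [window("N" * 300)], background=None) == []

    def test_two_planted_sites_both_reported(self):
        """Emulates the ddrA promoter carrying operator sites at -23 and -44."""
        pssm, _ = rdrm_fixture_pssm()
        s1 = "ATTCTGTTCTAAACTAAAT"[:17]
        s2 = "TTTATGTCTTGACCGTAAT"[:17]
        best = "".join("ACGT"[int(c)] for c in pssm.matrix.argmax(axis=1))
        rng = np.random.default_rng(4)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)]))
        # offsets are relative to the start codon at window position 500
        for off, site in ((-23, best), (-44, best)):
            seq[500 + off : 500 + off + 17] = list(site)
        hits = scan_promoters(pssm, [window("".join(seq))], background=None)
        offsets = sorted(h.offset for h in hits if h.p_value <= 1e-4)
        assert -44 in offsets and -23 in offsets

    def test_reverse_complement_equivariance(self):
        """Scanning a reversed window yields mirrored offsets, flipped strands."""
        pssm, _ = rdrm_fixture_pssm()
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        best = "".join("ACGT"[int(c)] for c in pssm.matrix.argmax(axis=1))
        seq = seq[:100] + best + seq[117:]
        fwd = scan_promoters(pssm, [window(seq)], p_threshold=1e-3,
                             background=None)
        rev = scan_promoters(pssm, [window(revcomp(seq))], p_threshold=1e-3,
                             background=None)
        n, w = len(seq), pssm.width
        mapped = sorted(
            (n - w - (h.offset + 500), {"+": "-", "-": "+"}[h.strand],
             round(h.score_bits, 6))
            for h in rev
        )
        direct = sorted(
            (h.offset + 500, h.strand, round(h.score_bits, 6)) for h in fwd
        )
        assert mapped == direct


class TestIupacConsensus:
    def test_dominant_base_wins(self):
        pssm = PSSM(np.array([[0.9, 0.03, 0.03, 0.04]]))
        assert iupac_consensus(pssm) == "A"

    def test_two_base_column_gets_degenerate_code(self):
        pssm = PSSM(np.array([[0.45, 0.45, 0.05, 0.05]]))
        assert iupac_consensus(pssm) == "M"

    def test_compatibility_counting_slides_to_best_offset(self):
        assert consensus_match_positions("AAACGTAAA", "CGT") == 3


class TestDiscoverMotifs:
    def test_exact_planted_17mer_is_recovered_sharply(self):
        # deliberately non-palindromic so posteriors cannot split strands
        site = "ATCGGATTACCAGTTCA"
        rng = np.random.default_rng(6)
        seqs = []
        for _ in range(50):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
            pos = int(rng.integers(0, 120 - 17))
            seqs.append(s[:pos] + site + s[pos + 17 :])
        res = discover_motifs(seqs, width_range=(17, 17), mode="any",
                              n_starts=5, seed=0)
        best = res[0].pssm
        mats = [best.matrix, best.matrix[::-1, ::-1]]
        assert any((m.max(axis=1) >= 0.9).all() for m in mats)

    def test_palindrome_mode_output_is_self_reverse_complement(self):
        site = "TTATGTCATTGACATAA"
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(20):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
            seqs.append(s[:40] + site + s[57:])
        res = discover_motifs(seqs, width_range=(17, 17), mode="palindrome",
                              n_starts=3, seed=0)
        m = res[0].pssm.matrix
        assert np.allclose(m, m[::-1, ::-1], atol=1e-9)

    def test_background_sequences_score_far_below_planted_sequences(self):
        """Pure i.i.d. background is separable from planted data: the null
        model's ZOOPS log-likelihood stays under half the planted one and
        its matrix is less informative."""
        fixture, _ = rdrm_fixture_pssm()
        rng = np.random.default_rng(8)
        null = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
            for _ in range(40)
        ]
        planted = []
        for s in null:
            site = fixture.sample_site(rng)
            pos = int(rng.integers(0, 600 - 17))
            planted.append(s[:pos] + site + s[pos + 17 :])
        res_null = discover_motifs(null, width_range=(17, 17), mode="any",
                                   n_starts=5, seed=0)
        res_planted = discover_motifs(planted, width_range=(17, 17),
                                      mode="any", n_starts=5, seed=0)
        assert (
            res_null[0].log_likelihood
            < 0.5 * res_planted[0].log_likelihood
        )
        assert (
            res_null[0].pssm.information_content()
            < res_planted[0].pssm.information_content()
        )

    def test_em_objective_is_monotone_nondecreasing(self):
        rng = np.random.default_rng(9)
        seqs = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
            for _ in range(10)
        ]
        site = "TTATGTCATTGACATAA"
        seqs = [s[:30] + site + s[47:] for s in seqs[:7]] + seqs[7:]
        for mode in ("any", "palindrome"):
            res = discover_motifs(seqs, width_range=(16, 17), mode=mode,
                                  n_starts=3, seed=1)
            for r in res:
                trace = np.array(r.objective_trace)
                assert len(trace) >= 2
                assert np.all(np.diff(trace) >= -1e-8)

    def test_all_n_sequences_are_an_error(self):
        with pytest.raises(ValueError):
            discover_motifs(["N" * 50] * 6, width_range=(15, 15), n_starts=1)


class TestMemeIO:
    def test_round_trip_and_biopython_cross_read(self, tmp_path):
        pssm, _ = rdrm_fixture_pssm()
        path = tmp_path / "m.meme"
        write_meme([pssm], str(path))
        back = read_meme(str(path))
        assert len(back) == 1
        assert np.allclose(back[0].matrix, pssm.matrix, atol=1e-6)
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        assert len(parsed) == 1
        bio_mat = np.array(
            [parsed[0].pwm[b] for b in "ACGT"]
        ).T
        assert np.allclose(bio_mat, pssm.matrix, atol=1e-4)


class TestAlignSites:
    def test_alignment_is_deterministic_and_common_width(self):
        sites = load_rdrm_sites()["site"].tolist()
        a1 = align_sites(sites, width=17)
        a2 = align_sites(sites, width=17)
        assert a1 == a2
        assert {len(s) for s in a1} == {17}
        # every aligned window is a substring of its source site
        assert all(w in s for w, s in zip(a1, sites))
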