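import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from fsomtype.io import MotifSet
from fsomtype.profiles import Profile
from fsomtype.stats import (binwise_border_test, fdr_adjust, iupac_to_regex,
                            motif_enrichment, motif_report, property_report,
                            reverse_complement, scan_motifs)
from fsomtype.stats import test_property as utest


class TestPropertyTest:
    def test_exact_two_sided_separated_groups(self):
        u, p, direction = utest([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * (1 / C(6,3))
        assert direction == "low"

    def test_identical_multisets_p_one(self):
        _, p, _ = utest([1.5, 2.5, 3.5], [1.5, 2.5, 3.5])
        assert p == 1.0

    def test_all_tied_returns_one_no_direction(self):
        _, p, d = utest([2, 2, 2], [2, 2, 2, 2])
        assert p == 1.0 and d is None

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            utest([1, 2], [1, 2, 3])

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(size=50), 1)       # ties guaranteed
        y = np.round(rng.normal(1.0, size=50), 1)
        _, p, d = utest(x, y)
        assert p < 1e-4 and d == "low"

    def test_direction_follows_median_difference(self):
        _, _, d = utest([5, 6, 7], [1, 2, 3])
        assert d == "high"

    def test_disjoint_null_calibration(self):
        """Type-I error of the two-sided U test at alpha=0.05 under a
        disjoint null (both groups drawn from the same distribution)."""
        rng = np.random.default_rng(11)
        reps, rej = 400, 0
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=60)
            _, p, _ = utest(x, y)
            rej += p <= 0.05
        rate = rej / reps
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2 * sd


class TestBinwiseBorderTest:
    def make_profiles(self, n, level, rng, delta=0.0):
        out = []
        for i in range(n):
            v = np.clip(rng.normal(level, 0.05, size=40), 0, 1) + delta
            out.append(Profile(f"p{i}", v, 20, 20, 10, 10))
        return out

    def test_shifted_cluster_flagged_high(self):
        rng = np.random.default_rng(5)
        bg = self.make_profiles(60, 0.4, rng)
        cl = self.make_profiles(25, 0.7, rng)
        res = binwise_border_test(cl, bg + cl)
        assert res.flag == "high"
        assert res.n_tested == 40
        assert res.n_high > 0.8 * res.n_tested

    def test_null_cluster_unflagged(self):
        rng = np.random.default_rng(6)
        bg = self.make_profiles(60, 0.5, rng)
        res = binwise_border_test(bg[:20], bg)
        assert res.flag is None

    def test_exact_threshold_not_flagged(self):
        # 16 of 20 is not strictly more than 80%
        assert not 16 > 0.8 * 20
        assert 17 > 0.8 * 20

    def test_no_testable_bins(self):
        rng = np.random.default_rng(7)
        cl = self.make_profiles(2, 0.5, rng)   # below min_n
        res = binwise_border_test(cl, cl, min_n=5)
        assert res.flag is None and res.n_tested == 0


class TestMotifEnrichment:
    def test_tail_matches_exhaustive_enumeration(self):
        # p_enrich = sum_{x>=5} C(10,x) C(90,10-x) / C(100,10)
        from math import comb
        expect = sum(comb(10, x) * comb(90, 10 - x) for x in range(5, 11)) \
            / comb(100, 10)
        p_enrich, _ = motif_enrichment(5, 10, 10, 100)
        assert p_enrich == pytest.approx(expect, rel=1e-12)

    def test_depletion_tail_matches_enumeration(self):
        from math import comb
        expect = sum(comb(12, x) * comb(38, 8 - x) for x in range(0, 3)) \
            / comb(50, 8)
        _, p_dep = motif_enrichment(2, 8, 12, 50)
        assert p_dep == pytest.approx(expect, rel=1e-12)

    def test_cluster_equals_background_both_tails_large(self):
        pe, pd_ = motif_enrichment(10, 100, 10, 100)
        assert pe >= 0.5 and pd_ >= 0.5

    def test_degenerate_full_counts(self):
        pe, pd_ = motif_enrichment(7, 7, 7, 7)
        assert pe == 1.0 and pd_ == 1.0

    def test_cluster_larger_than_background_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(1, 10, 1, 5)

    def test_tails_overlap_at_observed_value(self):
        pe, pd_ = motif_enrichment(4, 20, 30, 120)
        point = hypergeom.pmf(4, 120, 30, 20)
        assert pe + pd_ == pytest.approx(1.0 + point)


class TestFDR:
    def test_bh_hand_arithmetic(self):
        q, flags = fdr_adjust([0.01, 0.02, 0.04], level=0.05)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])
        assert flags.all()

    def test_single_p_identity(self):
        q, flags = fdr_adjust([0.2], level=0.05)
        assert q[0] == pytest.approx(0.2) and not flags[0]

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_input(self):
        q, flags = fdr_adjust([])
        assert q.size == 0 and flags.size == 0


class TestMotifScan:
    def test_iupac_matching(self):
        rx = iupac_to_regex("TGCATG")
        assert rx.search("AATGCATGAA")
        rx = iupac_to_regex("YGCR")
        assert rx.search("ATGCAA") and rx.search("ACGCGA")

    def test_reverse_complement(self):
        assert reverse_complement("TGCATG") == "CATGCA"

    def test_either_strand_hit(self):
        motifs = MotifSet([("FOX1", "TGCATG")])
        hits = scan_motifs({"fwd": "AATGCATGAA", "rev": "TTCATGCATT",
                            "none": "AAAAAAAAAA"}, motifs)
        assert bool(hits.loc["fwd", "FOX1"])
        assert bool(hits.loc["rev", "FOX1"])
        assert not bool(hits.loc["none", "FOX1"])

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(8)
        motifs = MotifSet([("M1", "TGCATG"), ("M2", "GGWCC")])
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60))
                for i in range(20)}
        flipped = {k: reverse_complement(v) for k, v in seqs.items()}
        h1 = scan_motifs(seqs, motifs)
        h2 = scan_motifs(flipped, motifs)
        pd.testing.assert_frame_equal(h1, h2)


class TestReports:
    def test_property_report_finds_planted_shift(self):
        rng = np.random.default_rng(3)
        assignments = {}
        rows = {}
        for i in range(120):
            cl = (0, 0) if i < 40 else (0, 1)
            assignments[f"e{i}"] = cl
            shift = 0.5 if cl == (0, 0) else 0.0
            rows[f"e{i}"] = {"psi": np.clip(rng.normal(0.3 + shift, 0.1), 0, 1)}
        rep = property_report(assignments, pd.DataFrame.from_dict(
            rows, orient="index"))
        high = rep[(rep.cluster == "Clu(0,0)") & (rep.property == "psi")]
        assert high.iloc[0]["significant"]
        assert high.iloc[0]["direction"] == "high"

    def test_motif_report_flags_exclusive(self):
        rng = np.random.default_rng(4)
        assignments = {f"e{i}": (0, i % 2) for i in range(100)}
        # cluster (0,0) events carry the motif, (0,1) events rarely
        seqs = {}
        for i in range(100):
            s = "".join(rng.choice(list("ACGT"), size=50))
            if i % 2 == 0 or rng.random() < 0.05:
                s = s[:20] + "TGCATG" + s[26:]
            seqs[f"e{i}"] = s
        hits = {"IE": scan_motifs(seqs, MotifSet([("FOX1", "TGCATG")]))}
        rep = motif_report(assignments, hits)
        assert not (rep.enriched & rep.depleted).any()
        r0 = rep[rep.cluster == "Clu(0,0)"].iloc[0]
        assert r0["enriched"] and not r0["depleted"]
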