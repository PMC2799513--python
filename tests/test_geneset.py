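"""GSA maxmean scoring, enrichment tests, consensus signature, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import frdapipe as fp
from frdapipe.geneset import consensus_min_count
from frdapipe.qpcr_damage import ConfigurationError, DataError

from conftest import make_labels, random_matrix
from oracles import hypergeom_tail_oracle, maxmean_oracle


class TestMaxmean:
    @pytest.mark.parametrize("scores, expected", [
        ([0.0, 0.0, 0.0], 0.0),
        ([1.0, -2.0, 3.0], 4.0 / 3.0),
        ([-1.0, -1.0], -1.0),
    ])
    def test_hand_values(self, scores, expected):
        assert fp.maxmean(np.array(scores)) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            z = rng.normal(size=rng.integers(1, 40))
            assert fp.maxmean(z) == pytest.approx(maxmean_oracle(z.tolist()), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        z=st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=20),
        c=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_positive_homogeneity(self, z, c):
        za = np.array(z)
        assert fp.maxmean(c * za) == pytest.approx(c * fp.maxmean(za), abs=1e-9, rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(DataError):
            fp.maxmean(np.array([]))


class TestHypergeomTail:
    def test_trivial_tails(self):
        assert fp.hypergeom_tail(20, 5, 5, 0) == 1.0
        assert fp.hypergeom_tail(20, 5, 5, 6) == 0.0

    def test_worked_example(self):
        # 1 - (C(15,5) + 5*C(15,4)) / C(20,5)
        expected = 1 - (math.comb(15, 5) + 5 * math.comb(15, 4)) / math.comb(20, 5)
        assert fp.hypergeom_tail(20, 5, 5, 2) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.36610, abs=5e-6)

    def test_full_grid_against_enumeration(self):
        """Every (N<=25, K, n, k) grid point matches direct summation to 1e-12."""
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 4):
                    for k in range(0, min(K, n) + 2):
                        assert fp.hypergeom_tail(N, K, n, k) == pytest.approx(
                            hypergeom_tail_oracle(N, K, n, k), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(DataError):
            fp.hypergeom_tail(10, 12, 5, 1)


class TestFisherEnrichment:
    def test_hits_equal_universe_no_enrichment(self):
        uni = [f"g{i}" for i in range(10)]
        _, p = fp.fisher_enrichment(uni, uni, uni)
        assert p == pytest.approx(1.0)

    def test_right_tail_matches_hypergeometric(self):
        # 2x2 table (4,1,1,14): right tail = P(X >= 4) with N=20, K=5, n=5
        uni = [f"g{i}" for i in range(20)]
        hits = uni[:5]
        gene_set = uni[:4] + [uni[5]]
        _, p = fp.fisher_enrichment(hits, gene_set, uni)
        assert p == pytest.approx(fp.hypergeom_tail(20, 5, 5, 4), abs=1e-12)
        # enumeration: (C(5,4)C(15,1) + C(5,5)C(15,0)) / C(20,5) = 76/15504
        assert p == pytest.approx(76 / 15504, abs=1e-12)

    def test_disjoint_hits_p_one(self):
        uni = [f"g{i}" for i in range(12)]
        _, p = fp.fisher_enrichment(uni[:4], uni[4:8], uni)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError):
            fp.fisher_enrichment([], [], [])


class TestConsensusSignature:
    @pytest.mark.parametrize("fraction, n_sets, expected", [
        (0.25, 23, 6),   # 25% of 23 sets -> at least 6
        (0.25, 1, 1),
        (0.5, 4, 2),
        (0.1, 30, 3),    # exact multiple: 0.1*30 = 3, no float creep
    ])
    def test_min_count_is_ceiling(self, fraction, n_sets, expected):
        assert consensus_min_count(fraction, n_sets) == expected

    @settings(max_examples=100, derandomize=True)
    @given(fraction=st.floats(min_value=0.01, max_value=1.0),
           n_sets=st.integers(min_value=1, max_value=60))
    def test_min_count_matches_exact_ceiling(self, fraction, n_sets):
        from fractions import Fraction
        expected = max(1, math.ceil(Fraction(fraction) * n_sets))
        assert consensus_min_count(fraction, n_sets) == expected

    def test_membership_counting(self):
        sets = {"s1": ["a", "b"], "s2": ["a", "c"], "s3": ["b", "a"], "s4": ["d", "a"]}
        sig = fp.consensus_signature(sets, min_fraction=0.5)
        assert sig.attrs["min_count"] == 2
        assert set(sig.index) == {"a", "b"}
        assert sig.loc["a", "n_sets"] == 4

    def test_single_set_keeps_all_genes(self):
        sig = fp.consensus_signature({"s": ["x", "y"]}, min_fraction=0.25)
        assert set(sig.index) == {"x", "y"}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            fp.consensus_signature({"s": ["x"]}, min_fraction=0.0)

    def test_planted_six_of_23_included_five_excluded(self):
        universe = [f"g{i}" for i in range(300)]
        sets = fp.simulate_gene_sets(23, [30] * 23, {"g0": 6, "g1": 5}, universe, seed=3)
        sig = fp.consensus_signature(sets, min_fraction=0.25)
        assert "g0" in sig.index
        assert "g1" not in sig.index


class TestDirectionalOverlap:
    def test_disjoint_lists_empty(self):
        assert fp.directional_overlap({"a": "up"}, {"b": "down"}) == []

    def test_direction_mismatch_excluded(self):
        assert fp.directional_overlap({"g": "up"}, {"g": "down"}) == []

    def test_enumerated_example(self):
        a = {"g1": "up", "g2": "down", "g3": "up"}
        b = {"g2": "down", "g3": "down"}
        assert fp.directional_overlap(a, b) == ["g2"]

    def test_invalid_direction_rejected(self):
        with pytest.raises(DataError):
            fp.directional_overlap({"g": "sideways"}, {})

    def test_overlap_test_reports_hypergeometric_p(self):
        a = {f"g{i}": "up" for i in range(10)}
        b = {f"g{i}": "up" for i in range(5, 15)}
        res = fp.overlap_test(a, b, n_universe=100)
        assert res["k_observed"] == 5
        assert res["p_hypergeom"] == pytest.approx(fp.hypergeom_tail(100, 10, 10, 5))


class TestGsa:
    def test_identical_sets_identical_scores(self):
        m, labels = random_matrix(200, 5, 5, seed=30)
        genes = list(m.index[:20])
        catalog = fp.GeneSetCatalog({"s1": genes, "s2": list(genes)})
        res = fp.gsa(catalog, m, labels, n_perm=60, seed=1)
        assert res.loc["s1", "score"] == res.loc["s2", "score"]
        assert res.loc["s1", "p"] == res.loc["s2", "p"]

    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(31)
        labels = make_labels(8, 8)
        mat = rng.normal(size=(400, 16))
        mat[:20, :8] += 1.5  # uniform shift of the planted set's genes in cases
        m = pd.DataFrame(mat, index=[f"g{i:03}" for i in range(400)], columns=labels.index)
        sets = {"planted": list(m.index[:20])}
        sets.update({f"rand{j}": list(np.random.default_rng(j).choice(m.index[20:], 20, replace=False))
                     for j in range(20)})
        res = fp.gsa(fp.GeneSetCatalog(sets), m, labels, n_perm=100, seed=2)
        best = res["standardized"].abs().idxmax()
        assert best == "planted"
        assert res.loc["planted", "p"] == res["p"].min()

    def test_null_calibration_at_one_percent(self):
        """~1% of random sets flagged at p < 0.01 on a null matrix (3 binomial sd)."""
        m, labels = random_matrix(800, 10, 10, seed=32)
        rng = np.random.default_rng(33)
        sets = {f"s{j}": list(rng.choice(m.index, 25, replace=False)) for j in range(200)}
        res = fp.gsa(fp.GeneSetCatalog(sets), m, labels, n_perm=200, seed=3)
        frac = res["significant"].mean()
        sd = math.sqrt(0.01 * 0.99 / 200)
        assert abs(frac - 0.01) <= 3 * sd

    def test_pvalues_roughly_uniform_under_null(self):
        """Pooled null p-values across independent cohorts pass a KS uniformity check.

        Within one run all sets share the same permutation sample, so their
        p-values are mutually correlated and a single-run KS test misreads that
        correlation as non-uniformity; pooling across independently generated
        cohorts gives an approximately independent sample of 200 p-values.
        """
        from scipy import stats as sps
        pvals = []
        for rep in range(5):
            m, labels = random_matrix(400, 8, 8, seed=200 + rep)
            rng = np.random.default_rng(300 + rep)
            sets = {f"s{j}": list(rng.choice(m.index, 20, replace=False))
                    for j in range(40)}
            res = fp.gsa(fp.GeneSetCatalog(sets), m, labels, n_perm=200, seed=400 + rep)
            pvals.extend(res["p"].tolist())
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_restriction_drops_unknown_genes(self):
        m, labels = random_matrix(50, 4, 4, seed=36)
        catalog = fp.GeneSetCatalog({"s": list(m.index[:5]) + ["absent_gene"]})
        res = fp.gsa(catalog, m, labels, n_perm=60, seed=5)
        assert res.loc["s", "n_genes"] == 5
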