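"""Pattern extraction: local clustering, filtering cascade, assignment, covariates."""

import numpy as np
import pandas as pd
import pytest

import frdapipe as fp
from frdapipe.epig import EpigParams, SNR_SENTINEL, snr
from frdapipe.qpcr_damage import ConfigurationError, DataError

from conftest import make_labels, planted_pattern_config, random_matrix
from frdapipe import simulate_expression


def assignment_accuracy(matrix, truth, params=None):
    """Fraction of planted member genes assigned to their own pattern."""
    params = params or EpigParams()
    labels = pd.Series(
        ["case" if s.startswith("case") else "control" for s in matrix.columns],
        index=matrix.columns, name="group",
    )
    patterns = fp.extract_patterns(matrix, params, labels)
    if not patterns:
        return len(patterns), 0.0
    asg = fp.assign_genes(matrix, patterns, params.r_assign)
    correct = total = 0
    for members in truth.pattern_memberships.values():
        sub = asg.loc[members, "pattern"]
        majority = sub[sub != "orphan"].value_counts()
        top = majority.idxmax() if len(majority) else None
        correct += int((sub == top).sum())
        total += len(members)
    return len(patterns), correct / total


class TestLocalClusterSize:
    def test_identical_profiles_count_all_others(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        profiles = np.tile(base, (5, 1))
        assert fp.local_cluster_size(base, profiles, r_t=0.9) == 4

    def test_uncorrelated_profiles_count_zero(self):
        t = np.linspace(0, 2 * np.pi, 24)
        sinus = np.sin(t)
        linear = np.linspace(-1, 1, 24)
        profiles = np.stack([sinus, linear])
        assert fp.local_cluster_size(sinus, profiles, r_t=0.5) == 0

    def test_planted_cluster_recovered(self):
        rng = np.random.default_rng(40)
        shared = rng.normal(size=30)
        members = shared + rng.normal(0, 0.33, size=(50, 30))  # within-r ~0.9
        noise = rng.normal(size=(100, 30))
        profiles = np.vstack([members, noise])
        size = fp.local_cluster_size(members[0], profiles, r_t=0.7)
        assert size >= 45

    def test_zero_variance_profile_counts_zero(self):
        profiles = np.vstack([np.zeros(8), np.random.default_rng(0).normal(size=(3, 8))])
        assert fp.local_cluster_size(np.zeros(8), profiles, r_t=0.5) == 0


class TestSnr:
    def test_equal_group_means_zero(self):
        labels = np.array(["a", "a", "b", "b"])
        assert snr(np.array([0.0, 2.0, 1.0, 1.0]), labels) == pytest.approx(0.0)

    def test_degenerate_within_variance_sentinel(self):
        labels = np.array(["a", "a", "b", "b"])
        assert snr(np.array([0.0, 0.0, 1.0, 1.0]), labels) == SNR_SENTINEL

    def test_hand_computed_value(self):
        labels = np.array(["a", "a", "b", "b"])
        assert snr(np.array([0.0, 1.0, 2.0, 3.0]), labels) == pytest.approx(2.0)

    def test_single_group_fallback(self):
        labels = np.array(["a", "a", "a", "a"])
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        expected = abs(profile.mean()) / profile.std(ddof=1)
        assert snr(profile, labels) == pytest.approx(expected)


class TestExtractPatterns:
    def test_pure_noise_yields_no_patterns(self):
        m, labels = random_matrix(300, 14, 14, seed=41)
        assert fp.extract_patterns(m, EpigParams(m_t=10), labels) == []

    def test_planted_three_patterns_recovered(self, planted_pattern_cohort):
        matrix, labels, truth = planted_pattern_cohort
        patterns = fp.extract_patterns(matrix, EpigParams(), labels)
        assert len(patterns) == 3
        for p in patterns:
            assert p.local_cluster_size >= 10
            assert p.snr >= 1.0
            assert p.magnitude >= 0.5

    def test_duplicated_pattern_genes_still_three_patterns(self, planted_pattern_cohort):
        """Adding copies of one pattern's genes must not create a fourth pattern."""
        matrix, labels, truth = planted_pattern_cohort
        members = truth.pattern_memberships["pattern_1"][:20]
        dup = matrix.loc[members].copy()
        dup.index = [f"dup_{g}" for g in dup.index]
        stacked = pd.concat([matrix, dup])
        patterns = fp.extract_patterns(stacked, EpigParams(), labels)
        assert len(patterns) == 3

    def test_matrix_smaller_than_m_t_rejected(self):
        m, labels = random_matrix(5, 3, 3, seed=0)
        with pytest.raises(DataError):
            fp.extract_patterns(m, EpigParams(m_t=10), labels)

    def test_scale_invariance_of_extraction_and_assignment(self, planted_pattern_cohort):
        """Multiplying all profiles by c > 0 changes neither patterns nor assignment."""
        matrix, labels, _ = planted_pattern_cohort
        params = EpigParams(magnitude_t=0.0)  # magnitude is the one scale-dependent filter
        p1 = fp.extract_patterns(matrix, params, labels)
        p2 = fp.extract_patterns(matrix * 3.0, params, labels)
        assert [p.seed_gene for p in p1] == [p.seed_gene for p in p2]
        assert [p.local_cluster_size for p in p1] == [p.local_cluster_size for p in p2]
        a1 = fp.assign_genes(matrix, p1, 0.64)
        a2 = fp.assign_genes(matrix * 3.0, p2, 0.64)
        assert (a1["pattern"] == a2["pattern"]).all()
        assert a1["r"].to_numpy() == pytest.approx(a2["r"].to_numpy())

    def test_recovery_across_ten_seeds(self):
        """Exactly 3 patterns and >= 95% assignment accuracy on every seeded cohort."""
        for seed in range(10):
            cfg = planted_pattern_config(seed=500 + seed)
            matrix, labels, truth = simulate_expression(cfg)
            n_patterns, accuracy = assignment_accuracy(matrix, truth)
            assert n_patterns == 3, f"seed {seed}: {n_patterns} patterns"
            assert accuracy >= 0.95, f"seed {seed}: accuracy {accuracy}"


class TestAssignGenes:
    def test_gene_identical_to_representative(self, planted_pattern_cohort):
        matrix, labels, _ = planted_pattern_cohort
        patterns = fp.extract_patterns(matrix, EpigParams(), labels)
        rep = patterns[0].representative_profile
        extended = pd.concat([
            matrix,
            pd.DataFrame([rep], index=["rep_clone"], columns=matrix.columns),
        ])
        asg = fp.assign_genes(extended, patterns, 0.64)
        assert asg.loc["rep_clone", "pattern"] == patterns[0].id
        assert asg.loc["rep_clone", "r"] == pytest.approx(1.0)

    def test_uncorrelated_gene_is_orphan(self, planted_pattern_cohort):
        matrix, labels, _ = planted_pattern_cohort
        patterns = fp.extract_patterns(matrix, EpigParams(), labels)
        asg = fp.assign_genes(matrix, patterns, 0.64)
        noise_genes = matrix.index[150:]
        assert (asg.loc[noise_genes, "pattern"] == "orphan").mean() > 0.9

    def test_orphan_count_monotone_in_r_assign(self, planted_pattern_cohort):
        matrix, labels, _ = planted_pattern_cohort
        patterns = fp.extract_patterns(matrix, EpigParams(), labels)
        orphan_counts = [
            (fp.assign_genes(matrix, patterns, r)["pattern"] == "orphan").sum()
            for r in (0.3, 0.5, 0.64, 0.8, 0.95)
        ]
        assert orphan_counts == sorted(orphan_counts)

    def test_no_patterns_rejected(self):
        m, _ = random_matrix(10, 3, 3, seed=0)
        with pytest.raises(DataError):
            fp.assign_genes(m, [], 0.64)


class TestPatternCovariateCorrelation:
    def test_exact_linear_function_gives_unit_correlation(self):
        cov = np.linspace(0, 10, 20)
        r, p = fp.epig.correlate_pattern_covariate(2.0 * cov + 1.0, cov)
        assert abs(r) == pytest.approx(1.0)
        assert p < 1e-10

    def test_planted_loading_recovers_r2(self):
        """Planted expected r^2 = 0.3 observed within +-0.15 at n=28."""
        rng = np.random.default_rng(44)
        r2s = []
        for _ in range(10):
            cov = rng.normal(size=28)
            profile = np.sqrt(0.3) * (cov - cov.mean()) / cov.std() \
                + np.sqrt(0.7) * rng.normal(size=28)
            r, _ = fp.epig.correlate_pattern_covariate(profile, cov)
            r2s.append(r * r)
        assert np.mean(r2s) == pytest.approx(0.3, abs=0.15)

    def test_shuffled_covariate_mostly_nonsignificant(self):
        rng = np.random.default_rng(45)
        cov = rng.normal(size=28)
        profile = cov + rng.normal(0, 0.5, size=28)
        n_null = 0
        for _ in range(100):
            shuffled = rng.permutation(cov)
            _, p = fp.epig.correlate_pattern_covariate(profile, shuffled)
            n_null += p > 0.05
        assert n_null >= 90

    def test_constant_covariate_rejected(self):
        with pytest.raises(DataError):
            fp.epig.correlate_pattern_covariate(np.arange(5.0), np.ones(5))
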