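import itertools

import numpy as np
import pytest
from scipy import stats as sps

from refusion.stats import (
    align_component_sign,
    bh_fdr,
    correlate_with_clinical,
    correlate_with_reference,
    group_ttest_loadings,
    partial_correlation,
    spatial_similarity,
    summary_ttest,
    zscore_threshold_map,
)

from conftest import bh_bruteforce, pearson_oracle


class TestSignAlignment:
    def _instance(self, seed=0):
        rng = np.random.default_rng(seed)
        group = np.r_[np.ones(20, int), np.zeros(20, int)]
        loadings = [rng.standard_normal((40, 3)) for _ in range(2)]
        maps = [rng.standard_normal((3, 50)) for _ in range(2)]
        return loadings, maps, group

    def test_control_mean_dominates_after_alignment(self):
        loadings, maps, group = self._instance()
        al, _ = align_component_sign(loadings, maps, group)
        for A in al:
            for c in range(A.shape[1]):
                assert A[group == 0, c].mean() >= A[group == 1, c].mean()

    def test_idempotent_and_involutive(self):
        loadings, maps, group = self._instance(1)
        al, am = align_component_sign(loadings, maps, group)
        al2, am2 = align_component_sign(al, am, group)
        assert all(np.array_equal(a, b) for a, b in zip(al, al2))
        # negating aligned input restores the aligned orientation
        al3, am3 = align_component_sign([-a for a in al], [-m for m in am], group)
        assert all(np.array_equal(a, b) for a, b in zip(al, al3))
        assert all(np.array_equal(a, b) for a, b in zip(am, am3))


class TestGroupTTest:
    def test_identical_classes_null(self):
        x = np.arange(10.0)
        A = np.concatenate([x, x])[:, None]
        group = np.r_[np.ones(10, int), np.zeros(10, int)]
        df = group_ttest_loadings([A], group)
        assert df["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_shift_detected_only(self):
        hits, false_hits = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            group = np.r_[np.ones(50, int), np.zeros(50, int)]
            loadings = [rng.standard_normal((100, 4)) for _ in range(2)]
            for A in loadings:
                A[group == 1, 0] -= 1.5
            df = group_ttest_loadings(loadings, group)
            planted = df[df["component"] == 0]
            others = df[df["component"] != 0]
            hits += int((planted["q"] < 0.05).all())
            false_hits += int((others["q"] < 0.05).any())
        assert hits >= 18  # >= 90% power on the planted component
        assert false_hits <= 4

    def test_consistent_with_summary_ttest(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(15) + 0.4, rng.standard_normal(12)
        t_raw = sps.ttest_ind(a, b, equal_var=True).statistic
        t_sum, _, _ = summary_ttest(
            a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 12, variant="pooled"
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-10)


class TestSummaryTTest:
    def test_pyrosequencing_worked_example(self):
        # published pyrosequencing validation: 31.8+/-1.5% (n=10) vs
        # 21.9+/-3.2% (n=10) gives t = 8.9 at one decimal
        for variant in ("pooled", "welch"):
            t, _, p = summary_ttest(31.8, 1.5, 10, 21.9, 3.2, 10, variant=variant)
            assert round(t, 1) == 8.9
            assert p < 1e-6

    def test_equal_means_zero(self):
        t, _, p = summary_ttest(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            summary_ttest(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            summary_ttest(1, 1.0, 1, 2, 1.0, 10)


class TestCorrelations:
    def test_loading_equal_to_reference(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal(30)
        df = correlate_with_reference([ref[:, None]], ref)
        assert df["r_ref"].iloc[0] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((25, 2))
        ref = rng.standard_normal(25)
        df = correlate_with_reference([A], ref)
        for c in range(2):
            assert df[df.component == c]["r_ref"].iloc[0] == pytest.approx(
                pearson_oracle(A[:, c], ref), abs=1e-12
            )

    def test_clinical_effect_recovered(self, strong_cohort):
        mods, _, design, truth = strong_cohort
        tgt = truth.loadings[0][:, truth.target_index][:, None]
        df = correlate_with_clinical([tgt], design.clinical[["MMSE"]])
        # generator plants corr 0.4 between MMSE and the target loading
        assert df["r"].iloc[0] == pytest.approx(0.4, abs=0.15)

    def test_onset_age_patients_only(self, strong_cohort):
        _, _, design, truth = strong_cohort
        tgt = truth.loadings[0][:, truth.target_index][:, None]
        df = correlate_with_clinical([tgt], design.clinical[["onset_age"]])
        assert df["n"].iloc[0] == int((design.group == 1).sum())


class TestPartialCorrelation:
    def test_reference_equal_to_group_gives_zero(self):
        rng = np.random.default_rng(6)
        group = np.r_[np.ones(30, int), np.zeros(30, int)]
        x = rng.standard_normal(60) + group
        r, _ = partial_correlation(x, group.astype(float), group)
        assert abs(r) < 1e-10

    def test_group_independent_latent_matches_marginal(self):
        rng = np.random.default_rng(7)
        group = np.r_[np.ones(200, int), np.zeros(200, int)]
        z = rng.standard_normal(400)
        x = z + 0.5 * rng.standard_normal(400)
        y = z + 0.5 * rng.standard_normal(400)
        r_partial, _ = partial_correlation(x, y, group)
        r_marginal = pearson_oracle(x, y)
        assert r_partial == pytest.approx(r_marginal, abs=0.02)

    def test_matches_explicit_ols_residual_oracle(self):
        rng = np.random.default_rng(8)
        group = np.r_[np.ones(15, int), np.zeros(15, int)]
        x = rng.standard_normal(30) + 0.8 * group
        y = rng.standard_normal(30) - 0.5 * group
        Z = np.column_stack([np.ones(30), group])
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        r_oracle = pearson_oracle(x - H @ x, y - H @ y)
        r, _ = partial_correlation(x, y, group)
        assert r == pytest.approx(r_oracle, abs=1e-10)


class TestBHFDR:
    def test_worked_step_up_list(self):
        reject, q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones(self):
        reject, q = bh_fdr(np.ones(6))
        assert not reject.any() and np.allclose(q, 1.0)

    def test_single_pvalue_reduces_to_raw(self):
        reject, q = bh_fdr(np.array([0.04]), alpha=0.05)
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_matches_bruteforce_on_all_permutations(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0, 0.3, 5)
        for perm in itertools.permutations(range(5)):
            p = base[list(perm)]
            reject, _ = bh_fdr(p, alpha=0.05)
            assert np.array_equal(reject, bh_bruteforce(p, 0.05))

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(10)
        p = np.sort(rng.uniform(size=20))
        _, q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)


class TestThresholdedMaps:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(11)
        tm = zscore_threshold_map(rng.normal(5, 3, 1000), 2.0)
        assert tm.z_map.mean() == pytest.approx(0.0, abs=1e-12)
        assert tm.z_map.std() == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_tail_mass(self):
        rng = np.random.default_rng(12)
        tm = zscore_threshold_map(rng.standard_normal(100_000), 2.0)
        assert tm.mask.mean() == pytest.approx(0.0455, abs=0.003)

    def test_infinite_threshold_empty_mask(self):
        tm = zscore_threshold_map(np.arange(10.0), np.inf)
        assert not tm.mask.any()

    def test_constant_map_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_threshold_map(np.ones(10), 2.0)


class TestSpatialSimilarity:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(13)
        m = rng.standard_normal(200)
        assert spatial_similarity(m, m) == pytest.approx(1.0)
        assert spatial_similarity(m, -m) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(14)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        assert spatial_similarity(a, b) == pytest.approx(pearson_oracle(a, b), abs=1e-12)
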