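import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from connfrag.community import consensus_affiliation
from connfrag.io import hemisphere_submatrix
from connfrag.simulate import SyntheticConfig, generate_planted_pair_cohort
from connfrag.stats import (
    bonferroni,
    fit_ols,
    pairwise_module_ttests,
    partial_correlation_one_tailed,
    pearson_one_tailed,
    pearson_two_tailed,
    ttest_unpaired,
)


class TestPearsonOneTailed:
    def test_perfect_anticorrelation(self):
        res = pearson_one_tailed([1, 2, 3], [3, 2, 1], "negative")
        assert res.r == pytest.approx(-1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_r(self):
        res = pearson_one_tailed([1, 2, 3], [1, 2, 4], "positive")
        assert res.r == pytest.approx(0.9820, abs=1e-4)

    def test_wrong_direction_p_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 0.3, 50)
        res = pearson_one_tailed(x, y, "negative")
        assert res.p > 0.99

    def test_tails_sum_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        p_pos = pearson_one_tailed(x, y, "positive").p
        p_neg = pearson_one_tailed(x, y, "negative").p
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        y = 0.3 * x + rng.normal(0, 1, 40)
        res = pearson_one_tailed(x, y, "positive")
        ref = sps.pearsonr(x, y, alternative="greater")
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        res2 = pearson_two_tailed(x, y)
        ref2 = sps.pearsonr(x, y)
        assert res2.p == pytest.approx(ref2.pvalue, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_one_tailed([1, 1, 1], [1, 2, 3], "positive")
        with pytest.raises(ValueError, match="mismatch"):
            pearson_one_tailed([1, 2, 3], [1, 2], "positive")

    def test_type_one_error_calibrated_under_gaussian_null(self):
        """One-tailed rejection rate at alpha=0.05 over 10,000 null draws
        of n=90 lies in the binomial band [0.04, 0.06]."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 10_000
        x = rng.normal(0, 1, (n_sim, 90))
        y = rng.normal(0, 1, (n_sim, 90))
        for i in range(n_sim):
            if pearson_one_tailed(x[i], y[i], "positive").p < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_sim <= 0.06


class TestPartialCorrelation:
    def test_empty_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        plain = pearson_one_tailed(x, y, "positive")
        part = partial_correlation_one_tailed(x, y, None, "positive")
        assert part.r == pytest.approx(plain.r, abs=1e-12)
        assert part.p == pytest.approx(plain.p, abs=1e-12)

    def test_self_covariate_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation_one_tailed(x, y, y[:, None], "positive")

    def test_known_partial_correlation_recovered(self):
        """x = z + u, y = z + v with corr(u, v) = 0.5: the partial
        correlation of x and y given z is exactly 0.5 by construction."""
        rng = np.random.default_rng(6)
        n = 10_000
        z = rng.normal(0, 1, n)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        uv = rng.multivariate_normal([0, 0], cov, size=n)
        x = z + uv[:, 0]
        y = z + uv[:, 1]
        res = partial_correlation_one_tailed(x, y, z[:, None], "positive")
        assert res.r == pytest.approx(0.5, abs=0.05)
        assert res.p < 1e-6

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n = 60
        z1 = rng.normal(0, 1, n)
        z2 = rng.normal(0, 1, n)
        x = 0.5 * z1 - 0.2 * z2 + rng.normal(0, 1, n)
        y = 0.4 * z1 + 0.3 * z2 + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation_one_tailed(
            x, y, np.column_stack([z1, z2]), "positive", tails=2
        )
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_converges_to_plain_pearson_with_independent_covariates(self):
        rng = np.random.default_rng(8)
        n = 10_000
        x = rng.normal(0, 1, n)
        y = 0.3 * x + rng.normal(0, 1, n)
        z = rng.normal(0, 1, (n, 2))  # independent of both
        plain = pearson_one_tailed(x, y, "positive")
        part = partial_correlation_one_tailed(x, y, z, "positive")
        assert part.r == pytest.approx(plain.r, abs=0.01)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="rank"):
            partial_correlation_one_tailed(x, y, Z, "positive")


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_unpaired([1, 2, 3, 4], [1, 2, 3, 4], tails=2)
        assert t == 0.0
        assert p == 1.0

    def test_separated_groups(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1e-3, 4)
        y = 1 + rng.normal(0, 1e-3, 4)
        _, p = ttest_unpaired(x, y, tails=2)
        assert p < 0.01

    def test_one_tailed_is_half_of_two_tailed_in_direction(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.5, 1, 20)
        y = rng.normal(0.0, 1, 20)
        t2, p2 = ttest_unpaired(x, y, tails=2)
        t1, p1 = ttest_unpaired(x, y, tails=1, direction="positive")
        assert t1 == t2
        if t2 > 0:
            assert p1 == pytest.approx(p2 / 2, abs=1e-12)

    def test_welch_variant_differs_with_unequal_variances(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 5, 10)
        y = rng.normal(1, 0.1, 40)
        _, p_student = ttest_unpaired(x, y, tails=2, equal_var=True)
        _, p_welch = ttest_unpaired(x, y, tails=2, equal_var=False)
        assert p_student != p_welch

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1, 1, 1], [2, 2, 2], tails=2)


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals,alpha,adj,sig",
        [
            ([0.001] + [0.5] * 99, 0.05, 0.1, False),
            ([0.03], 0.05, 0.03, True),
            ([0.0004] + [0.5] * 99, 0.05, 0.04, True),
        ],
    )
    def test_adjustment(self, pvals, alpha, adj, sig):
        adjusted, mask = bonferroni(pvals, alpha)
        assert adjusted[0] == pytest.approx(adj)
        assert bool(mask[0]) is sig

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2], 0.05)


class TestFitOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        summ = fit_ols(y, pd.DataFrame({"x": x}))
        est, _ = summ.coefficients["x"]
        assert est == pytest.approx(2.0, abs=1e-9)
        assert summ.intercept == pytest.approx(1.0, abs=1e-9)
        assert summ.adjusted_R2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        summ = fit_ols(y, pd.DataFrame({"x": x}))
        assert abs(summ.adjusted_R2) < 0.01

    def test_r2_never_decreases_with_extra_predictor(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 200)
        noise_pred = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 1, 200)
        s1 = fit_ols(y, pd.DataFrame({"x": x}))
        s2 = fit_ols(y, pd.DataFrame({"x": x, "junk": noise_pred}))
        assert s2.R2 >= s1.R2 - 1e-12
        assert s2.adjusted_R2 <= s2.R2

    def test_rank_deficiency_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            fit_ols(x, pd.DataFrame({"a": x, "b": 2 * x}))


@pytest.fixture(scope="module")
def planted():
    cfg = SyntheticConfig(
        n_subjects=40, n_regions_per_hemisphere=14, n_modules_healthy=3,
        rich_club_size=0, seed=3,
    )
    cohort = generate_planted_pair_cohort(cfg, pair_effect=25.0, noise_sd=8.0)
    affs = {}
    for s in cohort.subjects:
        left = hemisphere_submatrix(s.connectome, cohort.parcellation, "L")
        rng = np.random.default_rng([1, int(s.subject_id[1:])])
        affs[s.subject_id] = consensus_affiliation(left, n_runs=10, rng=rng)
    return cohort, affs


class TestPairwiseModuleTTests:
    def test_planted_pair_detected(self, planted):
        cohort, affs = planted
        df = pairwise_module_ttests(cohort, affs, "wab_aq")
        i, j = cohort.ground_truth["planted_pair"]
        hit = df[(df["region_i"] == i) & (df["region_j"] == j)]
        assert bool(hit["significant"].iloc[0])

    def test_subject_order_invariance(self, planted):
        cohort, affs = planted
        df1 = pairwise_module_ttests(cohort, affs, "wab_aq")
        shuffled = dict(reversed(list(affs.items())))
        df2 = pairwise_module_ttests(cohort, shuffled, "wab_aq")
        pd.testing.assert_frame_equal(df1, df2)

    def test_small_group_skipped(self, planted):
        cohort, affs = planted
        # min_group larger than either group forces the gate
        df = pairwise_module_ttests(cohort, affs, "wab_aq", min_group=30)
        assert (df["skipped_reason"] == "group_too_small").all()
        assert df["t"].isna().all()

    def test_unknown_score_rejected(self, planted):
        cohort, affs = planted
        with pytest.raises(ValueError, match="score"):
            pairwise_module_ttests(cohort, affs, "nonexistent")

    def test_preservation_gate_excludes_damaged_subjects(self, planted):
        """Damaging the planted pair's regions in every subject empties the
        eligible pool for that pair."""
        cohort, affs = planted
        i, j = cohort.ground_truth["planted_pair"]
        for s in cohort.subjects:
            s.damage[i] = 0.9
            s.damage[j] = 0.9
        try:
            df = pairwise_module_ttests(cohort, affs, "wab_aq")
            hit = df[(df["region_i"] == i) & (df["region_j"] == j)]
            assert hit["skipped_reason"].iloc[0] == "group_too_small"
            assert hit["n_affiliated"].iloc[0] == 0
        finally:
            for s in cohort.subjects:
                s.damage.pop(i, None)
                s.damage.pop(j, None)

    def test_bonferroni_counts_only_executed_tests(self, planted):
        cohort, affs = planted
        df = pairwise_module_ttests(cohort, affs, "wab_aq")
        executed = df[df["skipped_reason"] == ""]
        assert len(executed) > 0
        m = len(executed)
        expected = np.minimum(1.0, executed["p_one_tailed"] * m)
        np.testing.assert_allclose(executed["p_bonferroni"], expected, atol=1e-12)
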