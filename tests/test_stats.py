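"""Statistical machinery: chi-square, Mann-Whitney, adjusted OR, cluster
check, EM imputation — each against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from stratcare.errors import ConvergenceError, DataError, ZeroMarginError
from stratcare.stats import (
    adjusted_logistic_or,
    cluster_effect_check,
    em_impute_endpoints,
    mann_whitney_u,
    pearson_chi2,
)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "cells,expected,dp",
        [
            ((251, 332, 261, 107), 70.51, 2),  # intensity-by-arm table
            ((523, 60, 233, 135), 96.41, 2),   # adherence-by-arm table
            ((166, 376, 107, 241), 0.001, 3),  # dropout-by-arm table
        ],
    )
    def test_printed_trial_statistics(self, cells, expected, dp):
        assert round(pearson_chi2(*cells), dp) == expected

    def test_independent_proportional_table_is_zero(self):
        assert pearson_chi2(10, 20, 30, 60) == pytest.approx(0.0)

    def test_zero_margin_signalled(self):
        with pytest.raises(ZeroMarginError):
            pearson_chi2(0, 0, 5, 5)

    def test_negative_count_rejected(self):
        with pytest.raises(DataError):
            pearson_chi2(-1, 2, 3, 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_swap_invariance_and_scaling(self, cells):
        a, b, c, d = cells
        stat = pearson_chi2(a, b, c, d)
        assert stat == pytest.approx(pearson_chi2(c, d, a, b), rel=1e-12)
        assert stat == pytest.approx(pearson_chi2(b, a, d, c), rel=1e-12)
        assert pearson_chi2(3 * a, 3 * b, 3 * c, 3 * d) == pytest.approx(3 * stat, rel=1e-12)


class TestMannWhitney:
    def test_identical_constant_samples(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.u == 3 * 2 / 2

    def test_complete_separation_convention(self):
        # U counts pairs where x exceeds y.
        assert mann_whitney_u([1, 2], [3, 4]).u == 0.0
        assert mann_whitney_u([3, 4], [1, 2]).u == 4.0

    def test_small_samples_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(20)
        for _ in range(30):
            x = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            brute = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a, b in itertools.product(x, y)
            )
            assert mann_whitney_u(x, y).u == brute

    def test_tie_corrected_se(self):
        # No ties: SE reduces to sqrt(n1 n2 (n+1) / 12).
        res = mann_whitney_u([1.0, 2.0, 5.0], [3.0, 4.0, 6.0])
        assert res.se == pytest.approx(np.sqrt(3 * 3 * 7 / 12))
        # With ties the SE must shrink.
        tied = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 4.0, 6.0])
        assert tied.se < np.sqrt(3 * 3 * 7 / 12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])


def _simulate_binary(n, or_group, seed):
    rng = np.random.default_rng(seed)
    arm = np.where(rng.random(n) < 0.5, "stratified", "stepped")
    baseline = rng.normal(15, 5, n)
    eta = -0.5 + np.log(or_group) * (arm == "stratified") + 0.05 * (baseline - 15)
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"arm": arm, "baseline_phq9": baseline, "outcome": y})


class TestAdjustedLogisticOR:
    def test_matches_irls_oracle(self):
        from helpers import irls_logistic

        df = _simulate_binary(600, 1.5, seed=1)
        res = adjusted_logistic_or(df, "outcome")
        X = np.column_stack([
            (df["arm"] == "stratified").to_numpy(float),
            df["baseline_phq9"].to_numpy(),
        ])
        beta = irls_logistic(X, df["outcome"].to_numpy())
        assert np.log(res.odds_ratio) == pytest.approx(beta[1], abs=1e-6)

    def test_balanced_covariate_close_to_cross_product(self):
        """When the covariate is balanced across groups the adjusted OR is
        close to the 2x2 cross-product odds ratio."""
        df = _simulate_binary(20_000, 2.0, seed=2)
        res = adjusted_logistic_or(df, "outcome")
        g = df["arm"] == "stratified"
        y = df["outcome"] == 1
        a, b = (g & y).sum(), (g & ~y).sum()
        c, d = (~g & y).sum(), (~g & ~y).sum()
        crude = (a * d) / (b * c)
        assert res.odds_ratio == pytest.approx(crude, rel=0.05)

    def test_ci_ordering_invariant(self):
        df = _simulate_binary(500, 1.3, seed=3)
        res = adjusted_logistic_or(df, "outcome")
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_single_group_rejected(self):
        df = _simulate_binary(100, 1.0, seed=4)
        with pytest.raises(DataError):
            adjusted_logistic_or(df[df["arm"] == "stepped"], "outcome")

    def test_non_binary_outcome_rejected(self):
        df = _simulate_binary(100, 1.0, seed=5)
        df["outcome"] = df["baseline_phq9"]
        with pytest.raises(DataError):
            adjusted_logistic_or(df, "outcome")


class TestClusterEffectCheck:
    @staticmethod
    def _clustered(n, n_clusters, sigma, seed):
        rng = np.random.default_rng(seed)
        cluster = rng.integers(0, n_clusters, n)
        u = sigma * rng.standard_normal(n_clusters)
        baseline = rng.normal(15, 5, n)
        y = (rng.random(n) < expit(-0.3 + u[cluster] + 0.03 * (baseline - 15))).astype(float)
        return pd.DataFrame({"clinician_id": cluster, "baseline_phq9": baseline,
                             "rcsi_phq9": y})

    def test_statistic_nonnegative(self):
        df = self._clustered(400, 15, 0.0, seed=6)
        res = cluster_effect_check(df, "rcsi_phq9")
        assert res.minus2_delta_ll >= 0.0
        assert res.df == 1

    def test_large_cluster_variance_detected(self):
        detections = 0
        for seed in range(10):
            df = self._clustered(400, 20, 1.0, seed=100 + seed)
            res = cluster_effect_check(df, "rcsi_phq9")
            detections += res.p < 0.05
        assert detections >= 7

    def test_single_cluster_rejected(self):
        df = self._clustered(100, 1, 0.0, seed=7)
        with pytest.raises(DataError):
            cluster_effect_check(df, "rcsi_phq9")


class TestEMImputation:
    def test_no_missing_values_identity(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(50, 3)),
                          columns=["baseline_phq9", "post_phq9", "post_gad7"])
        res = em_impute_endpoints(df, predictor_cols=("baseline_phq9",))
        pd.testing.assert_frame_equal(res.table, df)
        assert res.n_iter == 0

    def test_bivariate_conditional_mean_oracle(self):
        """One missing endpoint: imputed value must equal the closed-form
        conditional mean under the converged (mu, Sigma)."""
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(12, 3, n)
        post = 4 + 0.7 * (x - 12) + rng.normal(0, 1.5, n)
        df = pd.DataFrame({"baseline_phq9": x, "post_phq9": post})
        df.loc[17, "post_phq9"] = np.nan
        res = em_impute_endpoints(df, endpoint_cols=("post_phq9",),
                                  predictor_cols=("baseline_phq9",),
                                  round_values=False)
        mu, cov = res.mean, res.cov
        expected = mu[1] + cov[1, 0] / cov[0, 0] * (df.loc[17, "baseline_phq9"] - mu[0])
        assert res.table.loc[17, "post_phq9"] == pytest.approx(expected, abs=1e-6)
        assert all(b >= a - 1e-9 for a, b in zip(res.loglik_trace, res.loglik_trace[1:]))

    def test_mcar_imputation_nearly_unbiased(self):
        """MCAR at 4%: the post-imputation mean stays within Monte-Carlo
        error of the complete-data mean over replicates."""
        rng = np.random.default_rng(10)
        deltas = []
        for _ in range(40):
            n = 500
            x = rng.normal(15, 5, n)
            post = 9 + 0.6 * (x - 15) + rng.normal(0, 4, n)
            df = pd.DataFrame({"baseline_phq9": x, "post_phq9": post})
            mask = rng.random(n) < 0.04
            truth = post.mean()
            df.loc[mask, "post_phq9"] = np.nan
            res = em_impute_endpoints(df, endpoint_cols=("post_phq9",),
                                      predictor_cols=("baseline_phq9",),
                                      round_values=False)
            deltas.append(res.table["post_phq9"].mean() - truth)
        assert abs(np.mean(deltas)) < 0.05

    def test_incomplete_predictors_rejected(self):
        df = pd.DataFrame({"baseline_phq9": [1.0, np.nan], "post_phq9": [2.0, 3.0]})
        with pytest.raises(DataError):
            em_impute_endpoints(df, endpoint_cols=("post_phq9",),
                                predictor_cols=("baseline_phq9",))

    def test_nonconvergence_signalled(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"baseline_phq9": rng.normal(size=80),
                           "post_phq9": rng.normal(size=80)})
        df.loc[:10, "post_phq9"] = np.nan
        with pytest.raises(ConvergenceError):
            em_impute_endpoints(df, endpoint_cols=("post_phq9",),
                                predictor_cols=("baseline_phq9",),
                                tol=0.0, max_iter=2)

    def test_bounds_clipping_and_rounding(self, completed_cohort):
        from stratcare.config import GAD7_BOUNDS, PHQ9_BOUNDS

        bounds = {"post_phq9": PHQ9_BOUNDS, "post_gad7": GAD7_BOUNDS}
        res = em_impute_endpoints(completed_cohort, bounds=bounds)
        out = res.table
        assert out["post_phq9"].notna().all()
        assert out["post_phq9"].between(0, 27).all()
        assert (out["post_phq9"] == out["post_phq9"].round()).all()
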