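import math

import numpy as np
import pytest

from jointglmm import (
    AnalysisConfig,
    CovarianceMatrix,
    build_stacked_design,
    fit_independent_models,
    fit_joint_model,
    grouped_pearson_statistic,
    marginal_probability,
    or_ci_table,
    pearson_gof,
)
from jointglmm.glmm import FittedJointModel, ModelError, fit_no_random_effect
from jointglmm.report import effect_table_frame
from jointglmm.simulate import SimulationTruth, simulate_cohort

from jointglmm import test_covariance_zero as covariance_zero_test
from jointglmm import test_variance_boundary as variance_boundary_test

from conftest import make_record


def synthetic_fit(theta1, theta2, columns, Sigma, se=None):
    """Assemble a FittedJointModel directly from given estimates (synthetic
    stand-in for a converged fit, used to exercise the reporting layer)."""
    p = len(columns)
    fit = FittedJointModel(
        theta1=np.asarray(theta1, float), theta2=np.asarray(theta2, float),
        columns=list(columns), outcome_names=("stunted", "anaemic"),
        Sigma=Sigma, loglik=-1.0, converged=True, n_iter=1, grad_norm=0.0,
        n_children=10, n_clusters=2, method="agq", nodes=7)
    fit.param_names = (
        [f"stunted:{c}" for c in columns] + [f"anaemic:{c}" for c in columns]
        + ["sigma11", "sigma22", "sigma12"])
    if se is not None:
        fit.cov_params = np.diag(np.asarray(se, float) ** 2)
    return fit


class TestOrCiTable:
    def test_or_equals_exp_estimate_and_ci_endpoints_exact(self):
        fit = synthetic_fit(
            [0.226, 0.531], [-0.712, 1.065],
            ["intercept", "wealth=Middle"],
            CovarianceMatrix(0.104, 0.314, 0.18),
            se=[0.186, 0.175, 0.186, 0.247, 0.01, 0.17, 0.141])
        rows = or_ci_table(fit)
        for row in rows:
            assert row.odds_ratio == pytest.approx(math.exp(row.estimate))
            if row.se is not None:
                assert row.ci_lower == pytest.approx(
                    math.exp(row.estimate - 1.96 * row.se))
                assert row.ci_upper == pytest.approx(
                    math.exp(row.estimate + 1.96 * row.se))
                assert row.ci_lower <= row.odds_ratio <= row.ci_upper

    def test_zero_estimate_gives_unit_or_symmetric_ci(self):
        fit = synthetic_fit([0.0], [0.0], ["intercept"],
                            CovarianceMatrix(0.1, 0.1, 0.0),
                            se=[0.5, 0.5, 0.1, 0.1, 0.1])
        row = or_ci_table(fit)[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.ci_lower * row.ci_upper == pytest.approx(1.0)

    def test_variance_rows_flagged_as_display_convention(self):
        fit = synthetic_fit([0.0], [0.0], ["intercept"],
                            CovarianceMatrix(0.104, 0.314, 0.18))
        frame = effect_table_frame(or_ci_table(fit))
        kinds = frame.set_index("variable")["kind"]
        assert kinds["sigma12"] == "variance-display"
        # exp of the covariance estimate lands in the OR column
        assert frame.loc[frame["variable"] == "sigma12", "OR"].iloc[0] == (
            pytest.approx(math.exp(0.18)))

    def test_missing_ses_emit_rows_without_ci(self):
        fit = synthetic_fit([0.3], [0.1], ["intercept"],
                            CovarianceMatrix(0.1, 0.1, 0.0))
        rows = or_ci_table(fit)
        assert all(r.ci_lower is None and r.p_value is None for r in rows)
        assert rows[0].odds_ratio == pytest.approx(math.exp(0.3))


class TestVarianceTests:
    def test_interior_lrt_reference_points(self):
        # T = 3.841 is the 95th percentile of chi2(1); T = 0 gives p = 1
        from jointglmm.report import VarianceTestResult, _lrt_statistic
        from scipy.stats import chi2
        assert chi2.sf(_lrt_statistic(3.841 / 2.0, 0.0), 1) == pytest.approx(
            0.050, abs=5e-4)
        assert chi2.sf(_lrt_statistic(0.0, 0.0), 1) == pytest.approx(1.0)

    def test_covariance_lrt_from_fits(self, codebook):
        truth = SimulationTruth(
            variables=(), theta1=np.zeros(1), theta2=np.zeros(1),
            Sigma=CovarianceMatrix(0.6, 0.6, 0.45), n_clusters=150,
            mean_children_per_cluster=6.0, seed=12)
        design = build_stacked_design(simulate_cohort(truth), [], codebook)
        cfg = AnalysisConfig(compute_se=False)
        joint = fit_joint_model(design, cfg)
        ind = fit_independent_models(design, cfg)
        res = covariance_zero_test(joint, ind)
        assert res.statistic >= 0.0
        assert res.null_distribution == "chi2(1)"
        assert 0.0 <= res.p_value <= 1.0
        # strong true covariance should be detected here
        assert res.p_value < 0.05

    def test_wald_and_score_agree_with_lrt_asymptotically(self, codebook):
        truth = SimulationTruth(
            variables=(), theta1=np.zeros(1), theta2=np.zeros(1),
            Sigma=CovarianceMatrix(0.6, 0.6, 0.3), n_clusters=120,
            mean_children_per_cluster=6.0, seed=21)
        design = build_stacked_design(simulate_cohort(truth), [], codebook)
        joint = fit_joint_model(design, AnalysisConfig())
        ind = fit_independent_models(design, AnalysisConfig(compute_se=False))
        lrt = covariance_zero_test(joint, ind, method="lrt")
        wald = covariance_zero_test(joint, ind, method="wald")
        score = covariance_zero_test(joint, ind, method="score",
                                     design=design)
        # the three tests are asymptotically equivalent; at this size they
        # should agree in order of magnitude and verdict
        for res in (lrt, wald, score):
            assert res.statistic >= 0.0
            assert 0.0 <= res.p_value <= 1.0
        assert wald.statistic == pytest.approx(lrt.statistic, rel=0.5)
        assert score.statistic == pytest.approx(lrt.statistic, rel=0.5)

    def test_negative_lrt_beyond_tolerance_rejected(self):
        with pytest.raises(ModelError, match="negative LRT"):
            variance_boundary_test(-1.0, 0.0)

    @pytest.mark.parametrize("T, expected_p", [(2.706, 0.050), (0.0, 1.0)])
    def test_boundary_mixture_reference_points(self, T, expected_p):
        res = variance_boundary_test(T / 2.0, 0.0)
        assert res.statistic == pytest.approx(T)
        assert res.p_value == pytest.approx(expected_p, abs=5e-4)
        assert res.null_distribution == "0.5*chi2(0)+0.5*chi2(1)"

    def test_mixture_p_never_exceeds_naive_chi2_p(self):
        from scipy.stats import chi2
        for T in np.linspace(0.01, 10.0, 40):
            mixture = variance_boundary_test(T / 2.0, 0.0).p_value
            naive = chi2.sf(T, 1)
            assert mixture <= naive + 1e-12

    def test_boundary_test_on_fitted_models(self, codebook):
        truth = SimulationTruth(
            variables=(), theta1=np.zeros(1), theta2=np.zeros(1),
            Sigma=CovarianceMatrix(1.0, 1.0, 0.0), n_clusters=100,
            mean_children_per_cluster=8.0, seed=3)
        design = build_stacked_design(simulate_cohort(truth), [], codebook)
        cfg = AnalysisConfig(compute_se=False)
        ind = fit_independent_models(design, cfg)
        reduced = fit_no_random_effect(design, 0)
        res = variance_boundary_test(ind[0], reduced, component="sigma11")
        assert res.p_value < 0.05   # variance of 1.0 is clearly nonzero


class TestPearsonGof:
    def test_hand_computed_toy(self):
        # two patterns of 10 children, observed successes 7 and 2,
        # expected probability one half in both
        stat = grouped_pearson_statistic(
            n_i=[10, 10], observed_prop=[0.7, 0.2], expected_prop=[0.5, 0.5])
        assert stat == pytest.approx(5.2)

    def test_perfect_fit_gives_zero(self):
        stat = grouped_pearson_statistic(
            n_i=[10, 20], observed_prop=[0.3, 0.8], expected_prop=[0.3, 0.8])
        assert stat == pytest.approx(0.0)

    def test_statistic_invariant_to_pattern_order(self):
        a = grouped_pearson_statistic([10, 20], [0.3, 0.8], [0.4, 0.7])
        b = grouped_pearson_statistic([20, 10], [0.8, 0.3], [0.7, 0.4])
        assert a == pytest.approx(b)

    def test_gof_on_fitted_model(self, codebook):
        truth = SimulationTruth(
            variables=("fever",), theta1=np.array([-0.2, 0.6]),
            theta2=np.array([0.1, -0.5]),
            Sigma=CovarianceMatrix(0.3, 0.3, 0.1), n_clusters=120,
            mean_children_per_cluster=6.0, seed=17)
        design = build_stacked_design(
            simulate_cohort(truth), ["fever"], codebook)
        fit = fit_joint_model(design, AnalysisConfig(compute_se=False))
        gof = pearson_gof(fit, design)
        assert gof.chi2 >= 0.0
        assert gof.n_patterns == 4        # two levels x two outcomes
        assert gof.ratio == pytest.approx(gof.chi2 / gof.df)
        assert gof.verdict in {"none detected", "overdispersion suspected"}

    def test_marginal_probability_against_monte_carlo(self):
        rng = np.random.default_rng(5)
        X = np.array([[1.0, 1.0]])
        theta = np.array([0.3, -0.8])
        sigma2 = 0.7
        u = rng.normal(0.0, math.sqrt(sigma2), size=200_000)
        mc = np.mean(1.0 / (1.0 + np.exp(-(X @ theta)[0] - u)))
        quad = marginal_probability(X, theta, sigma2)[0]
        assert quad == pytest.approx(mc, abs=0.005)
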