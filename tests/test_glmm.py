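import math

import numpy as np
import pytest
from scipy.integrate import simpson

from jointglmm import (
    AnalysisConfig,
    Codebook,
    CovarianceMatrix,
    SimulationTruth,
    VariableSpec,
    build_stacked_design,
    default_truth,
    fit_independent_models,
    fit_joint_model,
    fit_logistic,
    marginal_loglikelihood,
    simulate_cohort,
)
from jointglmm.glmm import JointMarginalLikelihood, ModelError

from conftest import make_record

FAST = AnalysisConfig(compute_se=False)


def grid_oracle_loglik(design, theta1, theta2, Sigma, span=6.0, n_grid=801):
    """Brute-force marginal log-likelihood by dense 2-D Simpson integration."""
    S = np.asarray(Sigma, dtype=float)
    P = np.linalg.inv(S)
    logdet = math.log(np.linalg.det(S))
    s = math.sqrt(max(S[0, 0], S[1, 1]))
    g = np.linspace(-span * s, span * s, n_grid)
    U1, U2 = np.meshgrid(g, g, indexing="ij")
    prior = (-math.log(2 * math.pi) - 0.5 * logdet
             - 0.5 * (P[0, 0] * U1**2 + 2 * P[0, 1] * U1 * U2
                      + P[1, 1] * U2**2))
    eta1 = design.X @ theta1
    eta2 = design.X @ theta2
    eta0 = np.where(design.outcome == 0, eta1, eta2)
    total = 0.0
    for c in range(design.n_clusters):
        m = design.cluster == c
        log_integrand = prior.copy()
        for eta_i, y_i, k_i in zip(eta0[m], design.y[m], design.outcome[m]):
            eta = eta_i + (U1 if k_i == 0 else U2)
            log_integrand += y_i * eta - np.logaddexp(0.0, eta)
        total += math.log(
            simpson(simpson(np.exp(log_integrand), x=g, axis=1), x=g))
    return total


def tiny_design(codebook):
    """2 clusters, 3 children, a binary covariate, both outcomes observed."""
    rng = np.random.default_rng(7)
    fevers = ["Yes", "No", "No"]
    records, k = [], 0
    for c, n_children in enumerate([2, 1]):
        for j in range(n_children):
            records.append(make_record(
                k, cluster=f"c{c}", covariates={"fever": fevers[k]},
                anaemic=int(rng.integers(2)), stunted=int(rng.integers(2))))
            k += 1
    return build_stacked_design(records, ["fever"], codebook)


def small_cohort_design(codebook, sigma, n_clusters=50, seed=0,
                        mean_children=6.0):
    truth = SimulationTruth(
        variables=("fever",), theta1=np.array([-0.3, 0.5]),
        theta2=np.array([0.2, -0.4]), Sigma=sigma, n_clusters=n_clusters,
        mean_children_per_cluster=mean_children, seed=seed)
    records = simulate_cohort(truth, codebook)
    return build_stacked_design(records, ["fever"], codebook), truth


class TestStackedDesign:
    def test_two_children_both_outcomes_four_rows(self, codebook):
        records = [make_record(i, anaemic=1, stunted=0) for i in range(2)]
        design = build_stacked_design(records, [], codebook)
        assert len(design.y) == 4
        assert design.n_children == 2

    def test_child_missing_one_outcome_contributes_one_row(self, codebook):
        records = [make_record(0, anaemic=None, stunted=1)]
        design = build_stacked_design(records, [], codebook)
        assert len(design.y) == 1
        assert design.outcome[0] == 0     # the stunting row

    def test_intercept_only_design_single_column(self, codebook):
        records = [make_record(i, anaemic=i % 2, stunted=0) for i in range(3)]
        design = build_stacked_design(records, [], codebook)
        assert design.columns == ["intercept"]
        assert np.all(design.X == 1.0)

    def test_no_usable_rows_rejected(self, codebook):
        with pytest.raises(ModelError, match="zero usable rows"):
            build_stacked_design([make_record(0)], [], codebook)


class TestMarginalLikelihood:
    def test_vanishing_sigma_collapses_to_bernoulli(self, codebook):
        # one child, both outcomes, theta = 0: ll -> 2 * ln(0.5)
        design = build_stacked_design(
            [make_record(0, anaemic=1, stunted=0)], [], codebook)
        ll = marginal_loglikelihood(
            design, np.zeros(1), np.zeros(1),
            CovarianceMatrix(1e-10, 1e-10, 0.0))
        assert ll == pytest.approx(2.0 * math.log(0.5), abs=1e-5)

    def test_agq_matches_grid_oracle_on_tiny_instance(self, codebook):
        design = tiny_design(codebook)
        rng = np.random.default_rng(1)
        theta1, theta2 = rng.normal(size=2), rng.normal(size=2)
        Sigma = np.array([[0.5, 0.2], [0.2, 0.5]])
        oracle = grid_oracle_loglik(design, theta1, theta2, Sigma)
        agq = marginal_loglikelihood(
            design, theta1, theta2, CovarianceMatrix.from_matrix(Sigma),
            nodes=25)
        assert abs(agq - oracle) < 1e-6

    def test_oracle_agreement_with_correlated_sigma(self, codebook):
        design = tiny_design(codebook)
        theta1 = np.array([0.4, -1.1])
        theta2 = np.array([-0.6, 0.9])
        Sigma = np.array([[0.8, -0.45], [-0.45, 0.6]])
        oracle = grid_oracle_loglik(design, theta1, theta2, Sigma)
        agq = marginal_loglikelihood(
            design, theta1, theta2, CovarianceMatrix.from_matrix(Sigma),
            nodes=25)
        assert abs(agq - oracle) < 1e-6

    def test_quadrature_converged_by_seven_nodes(self, codebook):
        design, truth = small_cohort_design(
            codebook, CovarianceMatrix(0.8, 0.6, 0.4))
        ll7 = marginal_loglikelihood(
            design, truth.theta1, truth.theta2, truth.Sigma, nodes=7)
        ll15 = marginal_loglikelihood(
            design, truth.theta1, truth.theta2, truth.Sigma, nodes=15)
        assert abs(ll7 - ll15) < 1e-4

    def test_laplace_is_single_node_agq(self, codebook):
        design = tiny_design(codebook)
        theta = np.array([0.1, -0.2])
        Sigma = CovarianceMatrix(0.5, 0.5, 0.1)
        ll_lap = marginal_loglikelihood(
            design, theta, theta, Sigma, method="laplace")
        ll_1 = JointMarginalLikelihood(design, nodes=1)(theta, theta, Sigma)
        assert ll_lap == pytest.approx(ll_1, abs=1e-12)

    def test_nonfinite_predictor_reports_cluster(self, codebook):
        design = tiny_design(codebook)
        with pytest.raises(ModelError, match="cluster"):
            marginal_loglikelihood(
                design, np.array([np.inf, 0.0]), np.zeros(2),
                CovarianceMatrix(0.5, 0.5, 0.0))


class TestJointFit:
    def test_independence_limit_matches_plain_logistic(self, codebook):
        # Sigma = 0 data: joint GLMM theta ~ no-random-effect logistic fit,
        # cross-checked against an established GLM implementation
        import statsmodels.api as sm

        design, _ = small_cohort_design(
            codebook, CovarianceMatrix(0.0, 0.0, 0.0),
            n_clusters=250, mean_children=6.0, seed=5)
        fit = fit_joint_model(design, FAST)
        for k, theta_hat in enumerate([fit.theta1, fit.theta2]):
            m = design.rows_for_outcome(k)
            ours = fit_logistic(design.X[m], design.y[m]).theta
            ref = sm.GLM(design.y[m], design.X[m],
                         family=sm.families.Binomial()).fit().params
            assert np.allclose(ours, ref, atol=1e-6)
            assert np.allclose(theta_hat, ref, atol=0.02)

    def test_factorization_identity_when_sigma12_zero(self, codebook):
        design, _ = small_cohort_design(
            codebook, CovarianceMatrix(0.6, 0.8, 0.3), seed=2)
        ind = fit_independent_models(design, FAST)
        ll_sum = ind[0].loglik + ind[1].loglik
        ll_joint_constrained = marginal_loglikelihood(
            design, ind[0].theta, ind[1].theta,
            np.diag([ind[0].sigma2, ind[1].sigma2]))
        assert abs(ll_joint_constrained - ll_sum) < 1e-6

    def test_joint_nests_independent_fits(self, codebook):
        design, _ = small_cohort_design(
            codebook, CovarianceMatrix(0.6, 0.8, 0.3), seed=3)
        joint = fit_joint_model(design, FAST)
        ind = fit_independent_models(design, FAST)
        assert joint.loglik >= ind[0].loglik + ind[1].loglik - 1e-8

    def test_uncorrelated_data_joint_and_independent_agree(self, codebook):
        design, _ = small_cohort_design(
            codebook, CovarianceMatrix(0.5, 0.5, 0.0),
            n_clusters=150, seed=4)
        ind = fit_independent_models(design, FAST)
        # the sigma12 = 0 reduction of the joint machinery reproduces the
        # separate univariate fits
        constrained = fit_joint_model(design, FAST, fix_sigma12=True)
        assert np.allclose(constrained.theta1, ind[0].theta, atol=1e-3)
        assert np.allclose(constrained.theta2, ind[1].theta, atol=1e-3)
        assert constrained.loglik == pytest.approx(
            ind[0].loglik + ind[1].loglik, abs=1e-5)
        # the unconstrained fit agrees up to the sampling noise of sigma12
        joint = fit_joint_model(design, FAST)
        assert np.allclose(joint.theta1, ind[0].theta, atol=0.05)
        assert np.allclose(joint.theta2, ind[1].theta, atol=0.05)

    def test_cluster_order_invariance(self, codebook):
        design, truth = small_cohort_design(
            codebook, CovarianceMatrix(0.5, 0.5, 0.2), n_clusters=30, seed=6)
        records = simulate_cohort(truth)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        d2 = build_stacked_design(shuffled, ["fever"], codebook)
        f1 = fit_joint_model(design, FAST)
        f2 = fit_joint_model(d2, FAST)
        assert np.allclose(f1.theta1, f2.theta1, atol=1e-8)
        assert f1.Sigma.sigma12 == pytest.approx(f2.Sigma.sigma12, abs=1e-8)

    def test_maximized_loglik_invariant_to_reference_recoding(self, codebook):
        design, truth = small_cohort_design(
            codebook, CovarianceMatrix(0.4, 0.4, 0.1), n_clusters=40, seed=8)
        records = simulate_cohort(truth)
        recoded = Codebook(variables=dict(codebook.variables))
        recoded.variables["fever"] = VariableSpec(("Yes", "No"), "No")
        d2 = build_stacked_design(records, ["fever"], recoded)
        f1 = fit_joint_model(design, FAST)
        f2 = fit_joint_model(d2, FAST)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)

    def test_standard_errors_reported_on_sigma_scale(self, codebook):
        design, _ = small_cohort_design(
            codebook, CovarianceMatrix(0.5, 0.5, 0.2), n_clusters=60, seed=9)
        fit = fit_joint_model(design, AnalysisConfig())
        assert fit.cov_params is not None
        se = fit.se
        assert se.shape == (len(fit.param_names),)
        assert np.all(np.isfinite(se))
        # parameter covariance symmetric PSD
        assert np.allclose(fit.cov_params, fit.cov_params.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(fit.cov_params) > -1e-8)
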