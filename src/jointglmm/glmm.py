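"""Bivariate binary GLMM with cluster-level random intercepts.

The model: for child i in cluster c and outcome k in {1: stunting,
2: anaemia},

    logit P(y_ik = 1 | u_c) = x_i' theta_k + u_ck,
    (u_c1, u_c2) ~ iid MVN(0, Sigma),   Sigma unstructured 2x2.

The marginal likelihood integrates the bivariate random effect out of each
cluster's Bernoulli product.  Integration is adaptive Gauss-Hermite
quadrature (AGQ): per-cluster mode-centred, curvature-scaled tensor-product
Gauss-Hermite; one node per dimension recovers the Laplace approximation.
Sigma is parameterized through its log-Cholesky factor, so the optimizer
works on an unconstrained space and the estimate is positive definite by
construction.  When sigma12 = 0 the likelihood factorizes and the model
reduces to two separate univariate GLMMs, which are also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .covariance import CovarianceMatrix
from .data import AnalysisConfig, ChildRecord, Codebook, encode_covariates

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stacked design


@dataclass
class StackedDesign:
    """Long format: one row per child x observed outcome.

    Rows are sorted by (cluster, child, outcome); cluster indices are dense
    in 0..C-1 so per-cluster reductions can use contiguous segments.  Both
    outcomes share the covariate row x_i but receive separate coefficient
    blocks theta1/theta2.
    """

    y: np.ndarray              # (n_rows,) 0/1 responses
    X: np.ndarray              # (n_rows, p) shared covariate rows
    outcome: np.ndarray        # (n_rows,) 0 = first outcome, 1 = second
    cluster: np.ndarray        # (n_rows,) dense cluster index, nondecreasing
    columns: list[str]
    outcome_names: tuple[str, str]
    cluster_labels: list[str]
    n_children: int
    n_dropped: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    @property
    def n_params_fixed(self) -> int:
        return 2 * self.X.shape[1]

    def __post_init__(self) -> None:
        if len(self.y) == 0:
            raise ModelError("stacked design has zero usable rows")
        if np.any(np.diff(self.cluster) < 0):
            raise ModelError("rows must be sorted by cluster")
        # first-row index of each cluster, for segmented reductions
        self.row_starts = np.searchsorted(
            self.cluster, np.arange(self.n_clusters))

    def rows_for_outcome(self, k: int) -> np.ndarray:
        return self.outcome == k


def build_stacked_design(
    records: Sequence[ChildRecord],
    variables: Sequence[str],
    codebook: Codebook,
    outcomes: tuple[str, str] = ("stunted", "anaemic"),
) -> StackedDesign:
    """Stack the two outcomes of each child into long-format model rows.

    Children missing one outcome contribute only the other row; children
    missing both (or any selected covariate) are dropped, with the count
    reported on the design.
    """
    enc = encode_covariates(records, codebook, variables)
    kept = [records[i] for i in enc.kept_indices]

    usable: list[tuple[str, str, int, np.ndarray, int]] = []
    dropped_outcomeless = 0
    for pos, r in enumerate(kept):
        vals = [getattr(r, name) for name in outcomes]
        if all(v is None for v in vals):
            dropped_outcomeless += 1
            continue
        for k, v in enumerate(vals):
            if v is not None:
                usable.append((r.cluster_id, r.child_id, k, enc.X[pos], int(v)))
    if not usable:
        raise ModelError("stacked design has zero usable rows")

    labels = sorted({row[0] for row in usable})
    label_index = {lab: i for i, lab in enumerate(labels)}
    # sort on stable ids so the design is independent of input record order
    usable.sort(key=lambda t: (label_index[t[0]], t[1], t[2]))

    y = np.array([t[4] for t in usable], dtype=float)
    X = np.array([t[3] for t in usable], dtype=float)
    outcome = np.array([t[2] for t in usable], dtype=int)
    cluster = np.array([label_index[t[0]] for t in usable], dtype=int)
    n_children = len({(t[0], t[1]) for t in usable})

    return StackedDesign(
        y=y, X=X, outcome=outcome, cluster=cluster, columns=enc.columns,
        outcome_names=outcomes, cluster_labels=labels,
        n_children=n_children,
        n_dropped=enc.n_dropped + dropped_outcomeless,
    )


# ---------------------------------------------------------------------------
# plain logistic ML (starting values; zero-variance reduced models)


@dataclass
class FittedLogisticModel:
    theta: np.ndarray
    columns: list[str]
    loglik: float
    cov: np.ndarray | None
    converged: bool
    n_obs: int

    @property
    def n_params(self) -> int:
        return len(self.theta)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def fit_logistic(
    X: np.ndarray, y: np.ndarray, columns: list[str] | None = None,
    max_iter: int = 100, tol: float = 1e-10,
) -> FittedLogisticModel:
    """Maximum-likelihood logistic regression by damped Newton-Raphson."""
    n, p = X.shape
    theta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ theta
        mu = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        H.flat[:: p + 1] += 1e-10  # guard perfect separation
        step = np.linalg.solve(H, grad)
        t = 1.0
        while t > 1e-6:
            cand = theta + t * step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if ll_c >= ll:
                break
            t *= 0.5
        theta = theta + t * step
        if abs(ll_c - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            ll = ll_c
            break
        ll_old = ll_c
        ll = ll_c
    mu = expit(X @ theta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return FittedLogisticModel(
        theta=theta, columns=list(columns or []), loglik=ll, cov=cov,
        converged=converged, n_obs=n)


# ---------------------------------------------------------------------------
# marginal likelihood machinery


def _segment_sum(values: np.ndarray, row_starts: np.ndarray) -> np.ndarray:
    """Sum `values` over contiguous cluster segments (works on 1-D or 2-D)."""
    return np.add.reduceat(values, row_starts, axis=0)


class JointMarginalLikelihood:
    """AGQ marginal log-likelihood of the bivariate model on a fixed design.

    Caches the per-cluster posterior modes between calls so repeated
    evaluations at nearby parameter values (line searches, finite
    differences) converge in a couple of Newton steps.
    """

    def __init__(self, design: StackedDesign, nodes: int = 7):
        if nodes < 1:
            raise ModelError("need at least one quadrature node per dimension")
        self.design = design
        self.nodes = nodes
        x, w = hermgauss(nodes)
        zi, zj = np.meshgrid(x, x, indexing="ij")
        self._z = np.stack([zi.ravel(), zj.ravel()], axis=1)      # (M, 2)
        self._logw = (np.log(w)[:, None] + np.log(w)[None, :]).ravel()
        self._z2 = (self._z**2).sum(axis=1)
        C = design.n_clusters
        self._u = np.zeros((C, 2))
        d = design
        self._idx2 = d.cluster * 2 + d.outcome  # grouping key (C x 2 cells)

    # -- internals ---------------------------------------------------------

    def _eta0(self, theta1: np.ndarray, theta2: np.ndarray) -> np.ndarray:
        d = self.design
        e1 = d.X @ theta1
        e2 = d.X @ theta2
        eta0 = np.where(d.outcome == 0, e1, e2)
        if not np.isfinite(eta0).all():
            bad = int(np.argmax(~np.isfinite(eta0)))
            raise ModelError(
                "non-finite linear predictor in cluster "
                f"{d.cluster_labels[d.cluster[bad]]}")
        return eta0

    def _penalized(self, eta0, u, P, logdet) -> np.ndarray:
        """h_c(u_c): conditional log-lik + MVN log-density, per cluster."""
        d = self.design
        eta = eta0 + u[d.cluster, d.outcome]
        rowll = d.y * eta - np.logaddexp(0.0, eta)
        cl = _segment_sum(rowll, d.row_starts)
        quad = (P[0, 0] * u[:, 0]**2 + 2 * P[0, 1] * u[:, 0] * u[:, 1]
                + P[1, 1] * u[:, 1]**2)
        return cl - LOG2PI - 0.5 * logdet - 0.5 * quad

    def _modes(self, eta0, P, logdet, tol=1e-10, max_iter=60):
        """Per-cluster posterior modes by damped Newton, vectorized."""
        d = self.design
        C = d.n_clusters
        u = self._u.copy()
        h = self._penalized(eta0, u, P, logdet)
        ncells = 2 * C
        for _ in range(max_iter):
            eta = eta0 + u[d.cluster, d.outcome]
            mu = expit(eta)
            S = np.bincount(self._idx2, weights=d.y - mu,
                            minlength=ncells).reshape(C, 2)
            W = np.bincount(self._idx2, weights=mu * (1.0 - mu),
                            minlength=ncells).reshape(C, 2)
            g = S - u @ P
            if np.max(np.abs(g)) < tol:
                break
            H11 = W[:, 0] + P[0, 0]
            H22 = W[:, 1] + P[1, 1]
            H12 = np.full(C, P[0, 1])
            det = H11 * H22 - H12**2
            d1 = (H22 * g[:, 0] - H12 * g[:, 1]) / det
            d2 = (-H12 * g[:, 0] + H11 * g[:, 1]) / det
            step = np.stack([d1, d2], axis=1)
            t = np.ones(C)
            for _ in range(20):  # per-cluster backtracking
                u_new = u + t[:, None] * step
                h_new = self._penalized(eta0, u_new, P, logdet)
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                t[worse] *= 0.5
            u = u + t[:, None] * step
            h = self._penalized(eta0, u, P, logdet)
        self._u = u
        # curvature at the mode
        eta = eta0 + u[d.cluster, d.outcome]
        mu = expit(eta)
        W = np.bincount(self._idx2, weights=mu * (1.0 - mu),
                        minlength=ncells).reshape(C, 2)
        return u, W

    def __call__(
        self,
        theta1: np.ndarray,
        theta2: np.ndarray,
        Sigma: CovarianceMatrix | np.ndarray,
    ) -> float:
        """Marginal log-likelihood at (theta1, theta2, Sigma)."""
        S = Sigma.matrix if isinstance(Sigma, CovarianceMatrix) else np.asarray(Sigma)
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        if det <= 0 or S[0, 0] <= 0:
            raise ModelError("Sigma must be positive definite for AGQ; "
                             "use the univariate/logistic path at the boundary")
        P = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        logdet = math.log(det)
        d = self.design
        eta0 = self._eta0(theta1, theta2)
        u, W = self._modes(eta0, P, logdet)

        # per-cluster inverse curvature and its Cholesky factor A
        H11 = W[:, 0] + P[0, 0]
        H22 = W[:, 1] + P[1, 1]
        H12 = P[0, 1]
        detH = H11 * H22 - H12**2
        M11 = H22 / detH
        M22 = H11 / detH
        M12 = -H12 / detH
        l11 = np.sqrt(M11)
        l21 = M12 / l11
        l22 = np.sqrt(np.maximum(M22 - l21**2, 1e-300))

        z = self._z                                   # (M, 2)
        # U_all[c, :, m] = u_c + sqrt(2) * A_c @ z_m
        sqrt2 = math.sqrt(2.0)
        U1 = u[:, 0, None] + sqrt2 * l11[:, None] * z[None, :, 0]
        U2 = (u[:, 1, None] + sqrt2 * (l21[:, None] * z[None, :, 0]
                                       + l22[:, None] * z[None, :, 1]))
        # conditional log-lik summed per cluster, all nodes at once
        Urow = np.where(
            (d.outcome == 0)[:, None], U1[d.cluster, :], U2[d.cluster, :])
        eta = eta0[:, None] + Urow                    # (n_rows, M)
        rowll = d.y[:, None] * eta - np.logaddexp(0.0, eta)
        cl = _segment_sum(rowll, d.row_starts)        # (C, M)
        quad = (P[0, 0] * U1**2 + 2 * P[0, 1] * U1 * U2 + P[1, 1] * U2**2)
        h = cl - LOG2PI - 0.5 * logdet - 0.5 * quad
        ll_c = (logsumexp(self._logw[None, :] + self._z2[None, :] + h, axis=1)
                + math.log(2.0) + np.log(l11 * l22))
        return float(ll_c.sum())


class UnivariateMarginalLikelihood:
    """AGQ marginal log-likelihood of a single-outcome random-intercept GLMM."""

    def __init__(self, y, X, cluster, row_starts, nodes: int = 7):
        self.y = y
        self.X = X
        self.cluster = cluster
        self.row_starts = row_starts
        self.C = len(row_starts)
        x, w = hermgauss(nodes)
        self._z = x
        self._logw = np.log(w)
        self._u = np.zeros(self.C)

    def _penalized(self, eta0, u, sigma2):
        eta = eta0 + u[self.cluster]
        rowll = self.y * eta - np.logaddexp(0.0, eta)
        cl = _segment_sum(rowll, self.row_starts)
        return cl - 0.5 * (LOG2PI + math.log(sigma2)) - 0.5 * u**2 / sigma2

    def __call__(self, theta: np.ndarray, sigma2: float) -> float:
        if sigma2 <= 0:
            raise ModelError("sigma2 must be positive for AGQ")
        eta0 = self.X @ theta
        u = self._u.copy()
        h = self._penalized(eta0, u, sigma2)
        for _ in range(60):
            eta = eta0 + u[self.cluster]
            mu = expit(eta)
            S = np.bincount(self.cluster, weights=self.y - mu, minlength=self.C)
            W = np.bincount(self.cluster, weights=mu * (1 - mu), minlength=self.C)
            g = S - u / sigma2
            if np.max(np.abs(g)) < 1e-10:
                break
            step = g / (W + 1.0 / sigma2)
            t = np.ones(self.C)
            for _ in range(20):
                h_new = self._penalized(eta0, u + t * step, sigma2)
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                t[worse] *= 0.5
            u = u + t * step
            h = self._penalized(eta0, u, sigma2)
        self._u = u
        eta = eta0 + u[self.cluster]
        mu = expit(eta)
        W = np.bincount(self.cluster, weights=mu * (1 - mu), minlength=self.C)
        a = 1.0 / np.sqrt(W + 1.0 / sigma2)          # scale = H^{-1/2}
        U = u[:, None] + math.sqrt(2.0) * a[:, None] * self._z[None, :]
        eta_all = eta0[:, None] + U[self.cluster, :]
        rowll = self.y[:, None] * eta_all - np.logaddexp(0.0, eta_all)
        cl = _segment_sum(rowll, self.row_starts)
        hmat = (cl - 0.5 * (LOG2PI + math.log(sigma2)) - 0.5 * U**2 / sigma2)
        ll_c = (logsumexp(self._logw[None, :] + self._z[None, :]**2 + hmat,
                          axis=1) + 0.5 * math.log(2.0) + np.log(a))
        return float(ll_c.sum())


def marginal_loglikelihood(
    design: StackedDesign,
    theta1: np.ndarray,
    theta2: np.ndarray,
    Sigma: CovarianceMatrix | np.ndarray,
    method: str = "agq",
    nodes: int = 7,
) -> float:
    """Marginal log-likelihood of the joint model at given parameters.

    ``method='laplace'`` is AGQ with a single node.
    """
    if method not in ("agq", "laplace"):
        raise ModelError(f"unknown method {method!r}")
    n = 1 if method == "laplace" else nodes
    return JointMarginalLikelihood(design, nodes=n)(
        np.asarray(theta1, float), np.asarray(theta2, float), Sigma)


# ---------------------------------------------------------------------------
# fitting


def _pack_chol(Sigma: CovarianceMatrix) -> tuple[float, float, float]:
    l11 = math.sqrt(max(Sigma.sigma11, 1e-10))
    l21 = Sigma.sigma12 / l11
    l22 = math.sqrt(max(Sigma.sigma22 - l21**2, 1e-10))
    return math.log(l11), l21, math.log(l22)


def _unpack_chol(a: float, b: float, c: float) -> CovarianceMatrix:
    l11 = math.exp(a)
    l22 = math.exp(c)
    return CovarianceMatrix(
        sigma11=l11 * l11, sigma12=b * l11, sigma22=b * b + l22 * l22)


@dataclass
class FittedJointModel:
    """Estimates and inferential metadata of the joint fit."""

    theta1: np.ndarray
    theta2: np.ndarray
    columns: list[str]
    outcome_names: tuple[str, str]
    Sigma: CovarianceMatrix
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_children: int
    n_clusters: int
    method: str
    nodes: int
    param_names: list[str] = field(default_factory=list)
    cov_params: np.ndarray | None = None   # on the reported scale
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.theta1) + len(self.theta2) + 3

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def estimates(self) -> np.ndarray:
        return np.concatenate([
            self.theta1, self.theta2,
            [self.Sigma.sigma11, self.Sigma.sigma22, self.Sigma.sigma12]])

    @property
    def se(self) -> np.ndarray | None:
        if self.cov_params is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))


def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                       rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + 2 * ei); fp = f(x + ei)
        fm = f(x - ei); fmm = f(x - 2 * ei)
        H[i, i] = (-fpp + 16 * fp - 30 * f0 + 16 * fm - fmm) / (12 * h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _chol_jacobian(a: float, b: float, c: float) -> np.ndarray:
    """d(sigma11, sigma22, sigma12)/d(a, b, c) for the log-Cholesky map."""
    ea, ec = math.exp(a), math.exp(c)
    return np.array([
        [2 * ea * ea, 0.0, 0.0],          # sigma11 = e^{2a}
        [0.0, 2 * b, 2 * ec * ec],        # sigma22 = b^2 + e^{2c}
        [b * ea, ea, 0.0],                # sigma12 = b e^a
    ])


_CHOL_BOUNDS = [(-6.0, 3.0), (-20.0, 20.0), (-6.0, 3.0)]


def fit_joint_model(
    design: StackedDesign,
    config: AnalysisConfig | None = None,
    start: FittedJointModel | None = None,
    fix_sigma12: bool = False,
) -> FittedJointModel:
    """Maximum-likelihood fit of the bivariate GLMM by AGQ.

    Starting values: per-outcome logistic fits for theta, 0.1*I for Sigma.
    Standard errors come from the inverse observed information (numerical
    Hessian at the optimum), delta-transformed to the reported scale.
    ``fix_sigma12=True`` constrains the cross-outcome covariance to zero,
    giving the separated-GLMM reduction within the joint machinery.
    """
    config = config or AnalysisConfig()
    p = design.X.shape[1]
    like = JointMarginalLikelihood(design, nodes=config.quadrature_nodes)

    if start is not None:
        x0 = np.concatenate([
            start.theta1, start.theta2, _pack_chol(start.Sigma)])
    else:
        m0, m1 = (design.rows_for_outcome(k) for k in (0, 1))
        th1 = fit_logistic(design.X[m0], design.y[m0]).theta
        th2 = fit_logistic(design.X[m1], design.y[m1]).theta
        x0 = np.concatenate([
            th1, th2, _pack_chol(CovarianceMatrix(0.1, 0.1, 0.0))])

    def neg_ll(x: np.ndarray) -> float:
        th1, th2 = x[:p], x[p:2 * p]
        Sigma = _unpack_chol(*x[2 * p:])
        return -like(th1, th2, Sigma)

    bounds = [(None, None)] * (2 * p) + list(_CHOL_BOUNDS)
    if fix_sigma12:
        bounds[2 * p + 1] = (0.0, 0.0)
        x0[2 * p + 1] = 0.0
    res = minimize(
        neg_ll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": config.max_iter,
                 "ftol": config.loglik_rel_tol,
                 "gtol": config.gradient_tol,
                 "maxcor": 25})
    x = res.x
    Sigma = _unpack_chol(*x[2 * p:])
    fit = FittedJointModel(
        theta1=x[:p].copy(), theta2=x[p:2 * p].copy(),
        columns=list(design.columns), outcome_names=design.outcome_names,
        Sigma=Sigma, loglik=-float(res.fun), converged=bool(res.success),
        n_iter=int(res.nit), grad_norm=float(np.max(np.abs(res.jac))),
        n_children=design.n_children, n_clusters=design.n_clusters,
        method="agq", nodes=config.quadrature_nodes,
        message=str(res.message),
    )
    names1 = [f"{design.outcome_names[0]}:{c}" for c in design.columns]
    names2 = [f"{design.outcome_names[1]}:{c}" for c in design.columns]
    fit.param_names = names1 + names2 + ["sigma11", "sigma22", "sigma12"]
    if not res.success:
        logger.warning("joint fit did not converge: %s", res.message)
    if config.compute_se:
        try:
            H = _numerical_hessian(neg_ll, x)
            cov_unc = np.linalg.pinv(H)
            J = np.eye(2 * p + 3)
            J[2 * p:, 2 * p:] = _chol_jacobian(*x[2 * p:])
            fit.cov_params = J @ cov_unc @ J.T
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian: standard errors unavailable")
            fit.cov_params = None
    return fit


@dataclass
class FittedUnivariateModel:
    """Single-outcome random-intercept GLMM fit."""

    outcome: str
    theta: np.ndarray
    columns: list[str]
    sigma2: float
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    n_clusters: int
    cov_params: np.ndarray | None = None   # (theta..., sigma2) scale

    @property
    def n_params(self) -> int:
        return len(self.theta) + 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _fit_univariate(
    y, X, cluster, columns, outcome, config: AnalysisConfig,
) -> FittedUnivariateModel:
    # compress to the clusters observed for this outcome
    uniq, dense = np.unique(cluster, return_inverse=True)
    order = np.argsort(dense, kind="stable")
    y, X, dense = y[order], X[order], dense[order]
    row_starts = np.searchsorted(dense, np.arange(len(uniq)))
    like = UnivariateMarginalLikelihood(
        y, X, dense, row_starts, nodes=config.quadrature_nodes)
    p = X.shape[1]
    th0 = fit_logistic(X, y).theta
    x0 = np.concatenate([th0, [0.5 * math.log(0.1)]])

    def neg_ll(x):
        return -like(x[:p], math.exp(2.0 * x[p]))

    bounds = [(None, None)] * p + [(-6.0, 3.0)]
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.max_iter,
                            "ftol": config.loglik_rel_tol,
                            "gtol": config.gradient_tol})
    sigma2 = math.exp(2.0 * res.x[p])
    fit = FittedUnivariateModel(
        outcome=outcome, theta=res.x[:p].copy(), columns=list(columns),
        sigma2=sigma2, loglik=-float(res.fun), converged=bool(res.success),
        n_iter=int(res.nit), n_obs=len(y), n_clusters=len(uniq))
    if config.compute_se:
        try:
            H = _numerical_hessian(neg_ll, res.x)
            cov_unc = np.linalg.pinv(H)
            J = np.eye(p + 1)
            J[p, p] = 2.0 * sigma2      # d sigma2 / d log-sd
            fit.cov_params = J @ cov_unc @ J.T
        except np.linalg.LinAlgError:
            fit.cov_params = None
    return fit


def fit_independent_models(
    design: StackedDesign, config: AnalysisConfig | None = None,
) -> tuple[FittedUnivariateModel, FittedUnivariateModel]:
    """Separate univariate GLMMs per outcome (the sigma12 = 0 reduction).

    With the cross-covariance fixed at zero the joint likelihood factorizes,
    so the sum of these two log-likelihoods equals the constrained joint
    log-likelihood.
    """
    config = config or AnalysisConfig()
    fits = []
    for k, name in enumerate(design.outcome_names):
        m = design.rows_for_outcome(k)
        fits.append(_fit_univariate(
            design.y[m], design.X[m], design.cluster[m],
            design.columns, name, config))
    return fits[0], fits[1]


def fit_no_random_effect(
    design: StackedDesign, k: int,
) -> FittedLogisticModel:
    """Plain logistic fit for outcome k: the zero-variance reduced model."""
    m = design.rows_for_outcome(k)
    return fit_logistic(design.X[m], design.y[m], columns=design.columns)
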