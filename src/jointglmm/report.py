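"""Variance-component tests, Pearson goodness-of-fit and odds-ratio tables.

Testing a variance component sits at the boundary of its parameter space
(a variance cannot be negative), so the likelihood-ratio statistic follows
a 50:50 mixture of a point mass at zero and chi-square(1) under the null.
The cross-outcome covariance is an interior parameter whenever both
variances are positive, so its LRT uses the plain chi-square(1) reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import chi2, norm

from .data import ChildRecord, Codebook
from .glmm import (
    FittedJointModel,
    FittedLogisticModel,
    FittedUnivariateModel,
    ModelError,
    StackedDesign,
)
from .screening import format_p

logger = logging.getLogger(__name__)

_SIGMA_LABELS = {
    "sigma11": ("variance", 0),
    "sigma22": ("variance", 1),
    "sigma12": ("covariance", None),
}


@dataclass
class EffectRow:
    """One reporting row: log-odds estimate with OR-scale interval."""

    outcome: str
    variable: str
    level: str
    estimate: float
    se: float | None
    odds_ratio: float
    ci_lower: float | None
    ci_upper: float | None
    p_value: float | None
    kind: str = "fixed"   # fixed | variance-display

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "variable": self.variable,
            "level": self.level, "estimate": self.estimate, "se": self.se,
            "OR": self.odds_ratio, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper, "p_value": self.p_value,
            "p_display": None if self.p_value is None else format_p(self.p_value),
            "kind": self.kind,
        }


def _split_column(column: str) -> tuple[str, str]:
    if "=" in column:
        var, level = column.split("=", 1)
        return var, level
    return column, ""


def or_ci_table(
    fit: FittedJointModel, alpha: float = 0.05, z_quantile: float | None = None,
) -> list[EffectRow]:
    """Exp-transformed coefficient table plus variance/covariance rows.

    OR = exp(estimate); CI = exp(estimate +/- z * SE); Wald two-sided p.
    The z quantile defaults to 1.96 at alpha = 0.05, matching conventional
    table reporting; pass ``z_quantile`` to use the exact normal quantile.
    Variance components are exponentiated too, as a display convention
    (kind='variance-display'), not an interpretable odds ratio.
    """
    if z_quantile is None:
        z_quantile = 1.96 if abs(alpha - 0.05) < 1e-12 else float(
            norm.ppf(1.0 - alpha / 2.0))
    se = fit.se
    if se is None:
        logger.warning("fit has no standard errors; emitting estimates only")
    rows: list[EffectRow] = []
    p = len(fit.columns)
    estimates = fit.estimates
    order = list(range(2 * p)) + [2 * p, 2 * p + 1, 2 * p + 2]
    for idx in order:
        name = fit.param_names[idx]
        est = float(estimates[idx])
        if idx < 2 * p:
            outcome, column = name.split(":", 1)
            variable, level = _split_column(column)
            kind = "fixed"
        else:
            component, which = name, _SIGMA_LABELS[name]
            outcome = ("both" if which[1] is None
                       else fit.outcome_names[which[1]])
            variable, level = component, which[0]
            kind = "variance-display"
        if se is not None and np.isfinite(se[idx]) and se[idx] > 0:
            s = float(se[idx])
            lo = math.exp(est - z_quantile * s)
            hi = math.exp(est + z_quantile * s)
            pval = 2.0 * float(norm.sf(abs(est / s)))
        else:
            s, lo, hi, pval = None, None, None, None
        rows.append(EffectRow(
            outcome=outcome, variable=variable, level=level, estimate=est,
            se=s, odds_ratio=math.exp(est), ci_lower=lo, ci_upper=hi,
            p_value=pval, kind=kind))
    return rows


def effect_table_frame(rows: Sequence[EffectRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


@dataclass
class VarianceTestResult:
    component: str            # sigma11 | sigma22 | sigma12
    method: str               # lrt | wald | score
    statistic: float
    null_distribution: str    # "chi2(1)" | "0.5*chi2(0)+0.5*chi2(1)"
    p_value: float


def _lrt_statistic(ll_full: float, ll_reduced: float, tol: float = 1e-4) -> float:
    # tol absorbs optimizer termination noise (relative ftol ~1e-9 on
    # log-likelihoods of order 1e3); genuine failures are far larger
    T = 2.0 * (ll_full - ll_reduced)
    if T < -tol:
        raise ModelError(
            f"negative LRT statistic {T:.3g}: reduced model has higher "
            "likelihood; the full-model optimizer likely failed")
    return max(T, 0.0)


def _score_statistic(
    design: StackedDesign,
    fit_independent: tuple[FittedUnivariateModel, FittedUnivariateModel],
) -> float:
    """Score test of sigma12 = 0 at the constrained (independent) MLE.

    Works in the unconstrained log-Cholesky space; the quadratic form
    g' H^{-1} g is invariant to the parameterization.  Gradient and
    observed information are numerical.
    """
    from .glmm import (
        JointMarginalLikelihood,
        _numerical_hessian,
        _pack_chol,
    )
    from .covariance import CovarianceMatrix as _CM

    p = design.X.shape[1]
    like = JointMarginalLikelihood(design, nodes=7)
    x0 = np.concatenate([
        fit_independent[0].theta, fit_independent[1].theta,
        _pack_chol(_CM(fit_independent[0].sigma2,
                       fit_independent[1].sigma2, 0.0))])

    def neg_ll(x):
        from .glmm import _unpack_chol
        return -like(x[:p], x[p:2 * p], _unpack_chol(*x[2 * p:]))

    h = 1e-4 * (1.0 + np.abs(x0))
    grad = np.array([
        (neg_ll(x0 + hi * ei) - neg_ll(x0 - hi * ei)) / (2 * hi)
        for hi, ei in zip(h, np.eye(len(x0)))])
    H = _numerical_hessian(neg_ll, x0)
    return float(grad @ np.linalg.pinv(H) @ grad)


def test_covariance_zero(
    fit_joint: FittedJointModel,
    fit_independent: tuple[FittedUnivariateModel, FittedUnivariateModel],
    method: str = "lrt",
    design: StackedDesign | None = None,
) -> VarianceTestResult:
    """Test H0: sigma12 = 0 against the unstructured alternative.

    With both variances positive, sigma12 = 0 is interior to the parameter
    space and the LRT statistic is chi-square(1) under H0.  The Wald
    alternative uses (sigma12_hat / SE)^2; the score alternative evaluates
    the efficient score at the constrained fit (needs ``design``).
    """
    if method == "lrt":
        ll0 = fit_independent[0].loglik + fit_independent[1].loglik
        T = _lrt_statistic(fit_joint.loglik, ll0)
    elif method == "wald":
        se = fit_joint.se
        if se is None:
            raise ModelError("Wald test needs standard errors")
        idx = fit_joint.param_names.index("sigma12")
        T = float((fit_joint.Sigma.sigma12 / se[idx]) ** 2)
    elif method == "score":
        if design is None:
            raise ModelError("score test needs the stacked design")
        T = max(0.0, _score_statistic(design, fit_independent))
    else:
        raise ModelError(f"unsupported method {method!r}")
    return VarianceTestResult(
        component="sigma12", method=method, statistic=T,
        null_distribution="chi2(1)", p_value=float(chi2.sf(T, df=1)))


def test_variance_boundary(
    fit_full: FittedUnivariateModel | FittedJointModel | float,
    fit_reduced: FittedLogisticModel | float,
    component: str = "sigma11",
) -> VarianceTestResult:
    """Boundary LRT of H0: one variance component equals zero.

    Accepts fitted models or raw log-likelihoods.  p = 0.5 * P(chi2_1 >= T)
    for T > 0 and 1 at T = 0: the 50:50 mixture null puts half its mass on
    the boundary point.
    """
    ll_full = fit_full if isinstance(fit_full, float) else fit_full.loglik
    ll_red = fit_reduced if isinstance(fit_reduced, float) else fit_reduced.loglik
    T = _lrt_statistic(ll_full, ll_red)
    p = 1.0 if T == 0.0 else 0.5 * float(chi2.sf(T, df=1))
    return VarianceTestResult(
        component=component, method="lrt", statistic=T,
        null_distribution="0.5*chi2(0)+0.5*chi2(1)", p_value=p)


@dataclass
class GofResult:
    chi2: float
    df: int
    ratio: float
    verdict: str
    n_patterns: int

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "ratio": self.ratio,
                "verdict": self.verdict, "n_patterns": self.n_patterns}


def marginal_probability(
    X: np.ndarray, theta: np.ndarray, sigma2: float, nodes: int = 40,
) -> np.ndarray:
    """Population-averaged P(y=1|x) = E_u[expit(x'theta + u)], u~N(0,sigma2)."""
    if sigma2 <= 0:
        return expit(X @ theta)
    z, w = hermgauss(nodes)
    u = math.sqrt(2.0 * sigma2) * z
    probs = expit((X @ theta)[:, None] + u[None, :])
    return probs @ (w / math.sqrt(math.pi))


def grouped_pearson_statistic(
    n_i: np.ndarray, observed_prop: np.ndarray, expected_prop: np.ndarray,
) -> float:
    """Sum_i n_i Sum_j (y_ij - pi_ij)^2 / pi_ij over the two categories."""
    n_i = np.asarray(n_i, dtype=float)
    y = np.asarray(observed_prop, dtype=float)
    pi = np.asarray(expected_prop, dtype=float)
    return float(np.sum(
        n_i * ((y - pi) ** 2 / pi + ((1 - y) - (1 - pi)) ** 2 / (1 - pi))))


def pearson_gof(
    fit: FittedJointModel,
    design: StackedDesign,
    overdispersion_bound: float = 1.2,
    nodes: int = 40,
) -> GofResult:
    """Grouped Pearson chi-square over identical-covariate patterns.

    Children are grouped by their covariate row, per outcome; for pattern i
    with n_i children and observed category proportions y_ij, the statistic
    sums n_i * (y_ij - pi_ij)^2 / pi_ij over the two response categories,
    against the model's population-averaged probabilities.  df = number of
    patterns minus fitted parameters; the statistic/df ratio below the
    configured bound reads as no overdispersion.
    """
    total = 0.0
    n_patterns = 0
    sigmas = (fit.Sigma.sigma11, fit.Sigma.sigma22)
    thetas = (fit.theta1, fit.theta2)
    for k in (0, 1):
        m = design.rows_for_outcome(k)
        Xk, yk = design.X[m], design.y[m]
        # group by identical covariate rows
        keys = [tuple(row) for row in Xk]
        frame = pd.DataFrame({"key": keys, "y": yk})
        grouped = frame.groupby("key", sort=True)["y"].agg(["mean", "count"])
        Xu = np.array([list(key) for key in grouped.index], dtype=float)
        pi = marginal_probability(Xu, thetas[k], sigmas[k], nodes=nodes)
        if np.any(pi <= 0) or np.any(pi >= 1):
            logger.warning("degenerate expected proportion; pattern skipped")
            keep = (pi > 0) & (pi < 1)
            grouped, pi = grouped[keep], pi[keep]
        total += grouped_pearson_statistic(
            grouped["count"].to_numpy(), grouped["mean"].to_numpy(), pi)
        n_patterns += len(grouped)
    df = max(n_patterns - fit.n_params, 1)
    ratio = total / df
    verdict = ("none detected" if ratio <= overdispersion_bound
               else "overdispersion suspected")
    return GofResult(chi2=total, df=df, ratio=ratio, verdict=verdict,
                     n_patterns=n_patterns)
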