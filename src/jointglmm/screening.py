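"""Univariate screening: weighted cross-tabulations, Pearson chi-square
tests, the p < 0.2 retention rule, and the planning sample-size formula.

Chi-square tests are computed on weighted counts without a design-effect
(Rao-Scott) correction, matching the conventional crosstab workflow for
survey summaries; this is not design-based inference and a warning notes so.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data import ChildRecord, Codebook

logger = logging.getLogger(__name__)


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningResult:
    variable: str
    outcome: str
    counts: pd.DataFrame      # levels x {0, 1}, weighted sums (exact)
    chi2: float
    df: int
    p_value: float
    retained: bool


def weighted_crosstab(
    records: Sequence[ChildRecord],
    variable: str,
    outcome: str,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Weighted level-by-outcome contingency table (cells = sums of weights).

    Records missing either the variable or the outcome are listwise deleted.
    Cells are kept exact internally; round only for display.
    """
    rows = []
    for r in records:
        label = r.covariates.get(variable)
        value = getattr(r, outcome, None)
        if label is None or value is None:
            continue
        rows.append((label, int(value), r.weight if use_weights else 1.0))
    if not rows:
        raise ScreeningError(
            f"empty table for {variable!r} x {outcome!r} after deletion")
    frame = pd.DataFrame(rows, columns=["level", "outcome", "w"])
    table = frame.pivot_table(index="level", columns="outcome", values="w",
                              aggfunc="sum", fill_value=0.0)
    table = table.reindex(columns=[0, 1], fill_value=0.0)
    if table.shape[0] < 2:
        raise ScreeningError(
            f"variable {variable!r} has a single observed level")
    return table


def row_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages across outcomes within each level row, table style."""
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def chi2_test(counts: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an L x 2 table, no continuity correction.

    Returns (statistic, df, p).  Zero expected cells are rejected with
    advice to merge categories.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ScreeningError(f"expected an Lx2 table with L>=2, got {table.shape}")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    if (expected <= 0).any():
        raise ScreeningError(
            "zero expected cell; merge sparse categories before testing")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


@dataclass
class ScreeningTable:
    results: list[ScreeningResult]
    retained_per_outcome: dict[str, list[str]]
    retained_union: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"variable": r.variable, "outcome": r.outcome, "chi2": r.chi2,
             "df": r.df, "p_value": r.p_value, "p_display": format_p(r.p_value),
             "retained": r.retained}
            for r in self.results
        ])


def screen_covariates(
    records: Sequence[ChildRecord],
    codebook: Codebook,
    alpha: float = 0.2,
    outcomes: Sequence[str] = ("stunted", "anaemic"),
    variables: Sequence[str] | None = None,
    use_weights: bool = True,
) -> ScreeningTable:
    """Chi-square screen of every covariate against each outcome.

    A variable is retained for an outcome iff p < alpha (strict); it enters
    the joint model if retained for either outcome (union rule).
    """
    if use_weights:
        logger.warning(
            "screening uses weighted counts without a design-effect "
            "correction; p-values are not design-based")
    variables = list(variables or codebook.variables)
    if not variables:
        raise ScreeningError("no variables to screen")
    results: list[ScreeningResult] = []
    retained: dict[str, list[str]] = {o: [] for o in outcomes}
    for var in variables:
        for outcome in outcomes:
            counts = weighted_crosstab(records, var, outcome, use_weights)
            stat, df, p = chi2_test(counts)
            keep = p < alpha
            results.append(ScreeningResult(
                variable=var, outcome=outcome, counts=counts,
                chi2=stat, df=df, p_value=p, retained=keep))
            if keep:
                retained[outcome].append(var)
    union = [v for v in variables if any(v in retained[o] for o in outcomes)]
    return ScreeningTable(results=results, retained_per_outcome=retained,
                          retained_union=union)


def required_sample_size(
    p: float, z: float = 1.96, d: float = 0.05
) -> tuple[float, int]:
    """Planning sample size n = z^2 p (1-p) / d^2; returns (exact, ceiling)."""
    if not (0.0 <= p <= 1.0):
        raise ScreeningError("p must be in [0, 1]")
    if d <= 0:
        raise ScreeningError("margin d must be positive")
    n = z * z * p * (1.0 - p) / (d * d)
    return n, int(math.ceil(n))


def format_p(p: float, resolution: float = 0.001) -> str:
    """Table-style p display: three decimals, '<0.001' below resolution."""
    if p < resolution:
        return f"<{resolution:g}"
    return f"{p:.3f}"
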