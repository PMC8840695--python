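"""Derivation of the two binary responses from biomarkers.

Anaemia: haemoglobin, adjusted for altitude, below 11 g/dl for children
6-59 months, with severity bands at 7 and 9 g/dl.  Stunting: height-for-age
z score (HAZ) strictly below -2 SD of the growth reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data import AnalysisConfig, ChildRecord

logger = logging.getLogger(__name__)

_FT_PER_M = 3.280839895  # metres -> feet

SEVERITY_NONE = "none"
SEVERITY_MILD = "mild"
SEVERITY_MODERATE = "moderate"
SEVERITY_SEVERE = "severe"


def altitude_adjustment_gdl(altitude_m: float | np.ndarray) -> float | np.ndarray:
    """Haemoglobin correction (g/dl) subtracted at a given altitude.

    Uses the CDC polynomial applied by the DHS program on altitude in
    thousands of feet: -0.032*A + 0.022*A^2, clamped at zero so the
    adjustment is never negative (it would otherwise be negative below
    roughly 440 m).
    """
    a_kft = np.asarray(altitude_m, dtype=float) * _FT_PER_M / 1000.0
    adj = np.maximum(0.0, -0.032 * a_kft + 0.022 * a_kft**2)
    return float(adj) if np.isscalar(altitude_m) else adj


def adjust_hb_for_altitude(
    hb_gdl: float | np.ndarray, altitude_m: float | np.ndarray
) -> float | np.ndarray:
    """Altitude-adjusted haemoglobin: raw Hb minus the altitude correction."""
    out = np.asarray(hb_gdl, dtype=float) - altitude_adjustment_gdl(
        np.asarray(altitude_m, dtype=float)
    )
    return float(out) if np.isscalar(hb_gdl) else out


@dataclass(frozen=True)
class AnaemiaStatus:
    anaemic: bool
    severity: str  # none | mild | moderate | severe


def classify_anaemia(adjusted_hb_gdl: float, cutoff_gdl: float = 11.0) -> AnaemiaStatus:
    """Binary and severity classification of adjusted haemoglobin.

    Severe < 7, moderate [7, 9), mild [9, cutoff); all comparisons strict
    at the upper edge, so Hb exactly at the cutoff is not anaemic.
    """
    hb = float(adjusted_hb_gdl)
    if hb < 7.0:
        return AnaemiaStatus(True, SEVERITY_SEVERE)
    if hb < 9.0:
        return AnaemiaStatus(True, SEVERITY_MODERATE)
    if hb < cutoff_gdl:
        return AnaemiaStatus(True, SEVERITY_MILD)
    return AnaemiaStatus(False, SEVERITY_NONE)


def classify_stunting(haz: float, cutoff_sd: float = -2.0) -> bool:
    """Stunted iff HAZ strictly below the cutoff (default -2 SD)."""
    return float(haz) < cutoff_sd


def classify_severe_stunting(haz: float, cutoff_sd: float = -3.0) -> bool:
    """Optional severe flag at HAZ < -3 SD (not used by the joint model)."""
    return float(haz) < cutoff_sd


def derive_outcomes(
    records: Sequence[ChildRecord],
    config: AnalysisConfig | None = None,
    min_age_months_anaemia: float = 6.0,
) -> list[ChildRecord]:
    """Fill the binary outcomes of each record from its biomarkers.

    Children with a recorded age below 6 months are excluded from the
    anaemia derivation (outcome left missing), matching survey practice.
    Records without altitude keep their raw haemoglobin (adjustment skipped
    and logged).
    """
    config = config or AnalysisConfig()
    out: list[ChildRecord] = []
    n_no_altitude = 0
    for r in records:
        anaemic = r.anaemic
        stunted = r.stunted
        if r.hb_gdl is not None:
            if r.age_months is not None and r.age_months < min_age_months_anaemia:
                anaemic = None
            else:
                if r.altitude_m is None:
                    n_no_altitude += 1
                    adjusted = r.hb_gdl
                else:
                    adjusted = adjust_hb_for_altitude(r.hb_gdl, r.altitude_m)
                anaemic = int(
                    classify_anaemia(adjusted, config.anaemia_cutoff_gdl).anaemic
                )
        if r.haz is not None:
            stunted = int(classify_stunting(r.haz, config.stunting_cutoff_sd))
        out.append(replace(r, anaemic=anaemic, stunted=stunted))
    if n_no_altitude:
        logger.warning(
            "derive_outcomes: %d records lacked altitude; Hb used unadjusted",
            n_no_altitude,
        )
    return out
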