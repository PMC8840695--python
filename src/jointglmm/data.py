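"""Data model, codebook-driven categorical encoding and CSV round-trip.

The unit of analysis is a child in a DHS-style cluster survey.  Records carry
survey structure (cluster id, sampling weight), biomarkers (haemoglobin,
height-for-age z score, altitude) and categorical covariates whose admissible
levels and reference categories live in a :class:`Codebook`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_NUMERIC_FIELDS = ("weight", "altitude_m", "hb_gdl", "haz", "age_months")
_OUTCOME_FIELDS = ("anaemic", "stunted")
_ID_FIELDS = ("child_id", "cluster_id", "household_id")
_DEFAULT_MISSING = ("", "na", "nan", "missing", ".")


class DataError(ValueError):
    """Raised on malformed input tables or codebook violations."""


@dataclass(frozen=True)
class VariableSpec:
    """Admissible levels of one categorical covariate."""

    levels: tuple[str, ...]
    reference: str
    role: str = "demographic"  # demographic | socio-economic
    missing_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(s.strip().lower() for s in self.levels)) != len(self.levels):
            raise DataError(f"duplicate levels in {self.levels}")
        if self.reference not in self.levels:
            raise DataError(
                f"reference {self.reference!r} not among levels {self.levels}"
            )


@dataclass
class Codebook:
    """Per-variable level lists, reference categories and missing codes.

    Labels are matched case-insensitively after trimming whitespace, since
    survey exports vary in casing.
    """

    variables: dict[str, VariableSpec]

    def canonical(self, variable: str, label: object) -> str | None:
        """Map a raw cell to its canonical level label, or None if missing.

        Raises :class:`DataError` for labels not in the codebook.
        """
        spec = self.variables[variable]
        if label is None or (isinstance(label, float) and math.isnan(label)):
            return None
        text = str(label).strip()
        low = text.lower()
        if low in _DEFAULT_MISSING or low in {m.lower() for m in spec.missing_codes}:
            return None
        for level in spec.levels:
            if level.strip().lower() == low:
                return level
        raise DataError(f"unknown label {text!r} for variable {variable!r}")

    def non_reference_levels(self, variable: str) -> list[str]:
        spec = self.variables[variable]
        return [lv for lv in spec.levels if lv != spec.reference]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        raw = yaml.safe_load(Path(path).read_text())
        variables = {
            name: VariableSpec(
                levels=tuple(v["levels"]),
                reference=v["reference"],
                role=v.get("role", "demographic"),
                missing_codes=tuple(v.get("missing_codes", ())),
            )
            for name, v in raw["variables"].items()
        }
        return cls(variables=variables)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "variables": {
                name: {
                    "levels": list(spec.levels),
                    "reference": spec.reference,
                    "role": spec.role,
                    "missing_codes": list(spec.missing_codes),
                }
                for name, spec in self.variables.items()
            }
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_codebook() -> Codebook:
    """Covariates of the joint model with their conventional reference levels.

    Reference levels follow the multivariable reporting convention: oldest age
    band, symptomatic ("Yes") for fever/diarrhoea, low birth weight, urban
    residence, richest wealth tertile, no maternal education.
    """
    return Codebook(
        variables={
            "sex": VariableSpec(("Male", "Female"), "Male", "demographic"),
            "age_group": VariableSpec(
                (">39 months", "20-39 months", "<20 months"),
                ">39 months",
                "demographic",
            ),
            "fever": VariableSpec(("Yes", "No"), "Yes", "demographic"),
            "diarrhoea": VariableSpec(("Yes", "No"), "Yes", "demographic"),
            "birth_weight": VariableSpec(
                ("<2500 g", ">=2500 g"), "<2500 g", "demographic"
            ),
            "residence": VariableSpec(("Urban", "Rural"), "Urban", "socio-economic"),
            "wealth": VariableSpec(
                ("Richer", "Middle", "Poorer"), "Richer", "socio-economic"
            ),
            "education": VariableSpec(
                ("No education", "Primary", "Post primary"),
                "No education",
                "socio-economic",
            ),
        }
    )


@dataclass
class ChildRecord:
    """One child: survey structure, biomarkers, covariates, binary outcomes."""

    child_id: str
    cluster_id: str
    household_id: str
    weight: float
    altitude_m: float | None = None
    hb_gdl: float | None = None
    haz: float | None = None
    age_months: float | None = None
    covariates: dict[str, str] = field(default_factory=dict)
    anaemic: int | None = None
    stunted: int | None = None

    def validate(self, codebook: Codebook | None = None) -> None:
        if not (self.weight > 0):
            raise DataError(f"child {self.child_id}: weight must be > 0")
        if self.hb_gdl is not None and not (2.0 < self.hb_gdl < 25.0):
            raise DataError(f"child {self.child_id}: hb {self.hb_gdl} outside (2, 25)")
        if self.haz is not None and not (-7.0 < self.haz < 7.0):
            raise DataError(f"child {self.child_id}: haz {self.haz} outside (-7, 7)")
        if self.altitude_m is not None and self.altitude_m < 0:
            raise DataError(f"child {self.child_id}: negative altitude")
        if codebook is not None:
            for var, label in self.covariates.items():
                if var not in codebook.variables:
                    raise DataError(f"variable {var!r} not in codebook")
                codebook.canonical(var, label)


@dataclass
class AnalysisConfig:
    """Tunable thresholds and fitting controls shared across pipeline stages."""

    anaemia_cutoff_gdl: float = 11.0
    stunting_cutoff_sd: float = -2.0
    screening_alpha: float = 0.2
    final_alpha: float = 0.05
    quadrature_nodes: int = 7
    gradient_tol: float = 1e-5
    loglik_rel_tol: float = 1e-9
    max_iter: int = 500
    seed: int = 0
    use_weights: bool = True
    compute_se: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.screening_alpha < 1.0):
            raise DataError("screening alpha must be in (0, 1)")
        if not (0.0 < self.final_alpha < 1.0):
            raise DataError("final alpha must be in (0, 1)")
        if self.quadrature_nodes < 1:
            raise DataError("quadrature nodes must be >= 1")
        for name in ("anaemia_cutoff_gdl", "stunting_cutoff_sd"):
            if not math.isfinite(getattr(self, name)):
                raise DataError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def _parse_float(cell: object, column: str, row: int) -> float | None:
    if cell is None:
        return None
    text = str(cell).strip()
    if text.lower() in _DEFAULT_MISSING:
        return None
    try:
        return float(text)
    except ValueError:
        raise DataError(f"unparseable numeric {text!r} in column {column!r}, row {row}")


def _parse_binary(cell: object, column: str, row: int) -> int | None:
    value = _parse_float(cell, column, row)
    if value is None:
        return None
    if value not in (0.0, 1.0):
        raise DataError(f"non-binary value {value} in column {column!r}, row {row}")
    return int(value)


def load_children_table(
    path: str | Path, codebook: Codebook
) -> list[ChildRecord]:
    """Read a child-level CSV into validated :class:`ChildRecord` objects.

    Missing codes map to missing values; unknown category labels are rejected.
    Row count is preserved (one record per data row).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in ("cluster_id", "weight"):
        if column not in frame.columns:
            raise DataError(f"missing mandatory column {column!r}")
    covariate_columns = [c for c in frame.columns if c in codebook.variables]
    records: list[ChildRecord] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        cells = dict(zip(frame.columns, row))
        weight = _parse_float(cells["weight"], "weight", row_index)
        if weight is None:
            raise DataError(f"missing weight in row {row_index}")
        covariates = {}
        for var in covariate_columns:
            label = codebook.canonical(var, cells[var])
            if label is not None:
                covariates[var] = label
        record = ChildRecord(
            child_id=str(cells.get("child_id", row_index)),
            cluster_id=str(cells["cluster_id"]),
            household_id=str(cells.get("household_id", cells["cluster_id"])),
            weight=weight,
            altitude_m=_parse_float(cells.get("altitude_m"), "altitude_m", row_index),
            hb_gdl=_parse_float(cells.get("hb_gdl"), "hb_gdl", row_index),
            haz=_parse_float(cells.get("haz"), "haz", row_index),
            age_months=_parse_float(cells.get("age_months"), "age_months", row_index),
            covariates=covariates,
            anaemic=_parse_binary(cells.get("anaemic"), "anaemic", row_index),
            stunted=_parse_binary(cells.get("stunted"), "stunted", row_index),
        )
        record.validate(codebook)
        records.append(record)
    return records


def records_to_frame(records: Iterable[ChildRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (covariates as plain columns)."""
    rows = []
    for r in records:
        row = {
            "child_id": r.child_id,
            "cluster_id": r.cluster_id,
            "household_id": r.household_id,
            "weight": r.weight,
            "altitude_m": r.altitude_m,
            "hb_gdl": r.hb_gdl,
            "haz": r.haz,
            "age_months": r.age_months,
            "anaemic": r.anaemic,
            "stunted": r.stunted,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_children_table(records: Sequence[ChildRecord], path: str | Path) -> None:
    """Write records as CSV; a write→read round-trip is the identity."""
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class EncodedDesign:
    """Reference-coded indicator table ready for model stacking."""

    X: np.ndarray                # (n_kept, 1 + sum(L_v - 1)) incl. intercept
    columns: list[str]           # "intercept", then "variable=level"
    kept_indices: np.ndarray     # positions into the input record sequence
    n_dropped: int               # listwise-deleted rows


def encode_covariates(
    records: Sequence[ChildRecord],
    codebook: Codebook,
    selected: Sequence[str],
) -> EncodedDesign:
    """Reference-level indicator coding of the selected covariates.

    A variable with L levels yields L-1 indicator columns; reference-level
    records get all-zero indicators.  Records missing any selected variable
    are listwise deleted and the dropped count reported.
    """
    for var in selected:
        if var not in codebook.variables:
            raise DataError(f"selected variable {var!r} not in codebook")
    kept: list[int] = []
    for i, r in enumerate(records):
        if all(r.covariates.get(v) is not None for v in selected):
            kept.append(i)
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("encode_covariates: listwise-deleted %d records", n_dropped)
    if not kept:
        raise DataError("no records left after listwise deletion")

    columns = ["intercept"]
    blocks = [np.ones((len(kept), 1))]
    for var in selected:
        observed = {records[i].covariates[var] for i in kept}
        if len(observed) < 2:
            raise DataError(
                f"variable {var!r} has a single observed level; non-identifiable"
            )
        for level in codebook.non_reference_levels(var):
            indicator = np.array(
                [1.0 if records[i].covariates[var] == level else 0.0 for i in kept]
            )
            blocks.append(indicator[:, None])
            columns.append(f"{var}={level}")
    X = np.hstack(blocks)
    return EncodedDesign(
        X=X, columns=columns, kept_indices=np.array(kept, dtype=int),
        n_dropped=n_dropped,
    )
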