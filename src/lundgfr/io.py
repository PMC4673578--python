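"""Tabular I/O: patient panels, truth tables, decision reports, age curves.

Panels are UTF-8 CSV with a header, "." decimal separator, creatinine in
μmol/L and cystatin C in mg/L.  The ``flags`` column holds semicolon-
separated clinical-flag names; empty cells are absent optionals.  Unknown
columns are rejected by name, and cell errors are reported with their row
and column so a malformed panel fails loudly rather than silently.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTruth
from .equations import EquationRegistry, MarkerBasis, applicable
from .equations import estimate as _estimate
from .errors import LundGFRError, PanelFormatError
from .types import ClinicalFlag, PatientRecord, Sex

REQUIRED_COLUMNS = ("patient_id", "age", "sex")
OPTIONAL_COLUMNS = (
    "height",
    "weight",
    "population",
    "creatinine",
    "cystatin_c",
    "flags",
    "measured_gfr",
)
PANEL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

_FLOAT_FIELDS = ("age", "height", "weight", "creatinine", "cystatin_c", "measured_gfr")


@dataclass(frozen=True)
class PatientPanel:
    """An ordered collection of patient records with source-row numbers."""

    records: tuple[PatientRecord, ...]
    row_numbers: tuple[int, ...]  # 1-based data-row numbers in the source file

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_cell(raw, row: int, column: str):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    text = str(raw).strip()
    if column in _FLOAT_FIELDS:
        try:
            return float(text)
        except ValueError:
            raise PanelFormatError(
                f"row {row}, column {column!r}: cannot parse {text!r} as a number"
            ) from None
    if column == "flags":
        try:
            return frozenset(
                ClinicalFlag(part.strip()) for part in text.split(";") if part.strip()
            )
        except ValueError as exc:
            raise PanelFormatError(f"row {row}, column 'flags': {exc}") from None
    if column == "sex":
        try:
            return Sex(text.lower())
        except ValueError:
            raise PanelFormatError(
                f"row {row}, column 'sex': expected 'female' or 'male', got {text!r}"
            ) from None
    return text


def read_panel(path_or_buffer, sep: str = ",") -> PatientPanel:
    """Read and validate a patient panel from a delimited table."""
    frame = pd.read_csv(path_or_buffer, sep=sep, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in PANEL_COLUMNS]
    if unknown:
        raise PanelFormatError(f"unknown column(s): {unknown}")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"missing required column(s): {missing}")

    records, rows = [], []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        kwargs = {}
        for column in frame.columns:
            kwargs[column] = _parse_cell(raw[column], idx, column)
        for column in REQUIRED_COLUMNS:
            if kwargs.get(column) is None:
                raise PanelFormatError(f"row {idx}: required column {column!r} is empty")
        kwargs.setdefault("flags", None)
        if kwargs["flags"] is None:
            kwargs["flags"] = frozenset()
        try:
            records.append(PatientRecord(**kwargs))
        except LundGFRError as exc:
            raise PanelFormatError(f"row {idx}: {exc}") from exc
        rows.append(idx)
    return PatientPanel(tuple(records), tuple(rows))


def panel_to_frame(records) -> pd.DataFrame:
    """Serialise patient records to a DataFrame in canonical column order."""
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "sex": rec.sex.value,
                "height": rec.height,
                "weight": rec.weight,
                "population": rec.population,
                "creatinine": rec.creatinine,
                "cystatin_c": rec.cystatin_c,
                "flags": ";".join(sorted(f.value for f in rec.flags)),
                "measured_gfr": rec.measured_gfr,
            }
        )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel(records, path) -> None:
    panel_to_frame(records).to_csv(path, index=False)


def truth_to_frame(truth: CohortTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "true_gfr": truth.true_gfr,
            "muscle_factor": truth.muscle_factor,
            "steroid_factor": truth.steroid_factor,
            "flags_true": [
                ";".join(sorted(f.value for f in flags)) for flags in truth.flags_true
            ],
            "expected_route": [r.value for r in truth.expected_route],
            "measured_gfr": truth.measured_gfr,
        }
    )


def write_decisions(decisions, patient_ids, path) -> None:
    """Write decision reports as JSON lines, one object per patient."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid, decision in zip(patient_ids, decisions):
            fh.write(json.dumps(decision.to_dict(pid)) + "\n")


# ---------------------------------------------------------------------------
# Age-sweep curve export
# ---------------------------------------------------------------------------


def export_age_curve(
    registry: EquationRegistry,
    equation_ids,
    sex: Sex | str,
    creatinine: float,
    age_grid,
    height_table: dict | None = None,
) -> pd.DataFrame:
    """eGFR as a function of age at a constant creatinine level.

    One row per (age, equation); an equation outside its age range at a
    given age contributes no row.  Height-based equations require a
    ``height_table`` mapping age (years) to height (cm); heights at
    intermediate ages are linearly interpolated.
    """
    sex = Sex(sex)
    specs = [registry.get(eid) for eid in equation_ids]
    table_ages = table_heights = None
    for spec in specs:
        if "height" in spec.required_fields:
            if not height_table:
                raise PanelFormatError(
                    f"equation {spec.equation_id!r} requires a height-for-age table"
                )
            table_ages = np.asarray(sorted(height_table), dtype=float)
            table_heights = np.asarray(
                [height_table[a] for a in sorted(height_table)], dtype=float
            )
    rows = []
    for age in age_grid:
        for spec in specs:
            height = None
            if "height" in spec.required_fields:
                height = float(np.interp(age, table_ages, table_heights))
            patient = PatientRecord(
                patient_id="<curve>",
                age=float(age),
                sex=sex,
                height=height,
                creatinine=float(creatinine),
                cystatin_c=None,
            )
            if spec.marker_basis is not MarkerBasis.creatinine:
                continue
            if not applicable(spec, patient):
                continue
            rows.append(
                {
                    "age": float(age),
                    "equation_id": spec.equation_id,
                    "egfr": _estimate(patient, spec).value,
                }
            )
    return pd.DataFrame(rows, columns=["age", "equation_id", "egfr"])


def read_height_table(path) -> dict:
    """Read an age→height table from a two-column CSV (age, height)."""
    frame = pd.read_csv(path)
    cols = [c.lower() for c in frame.columns]
    if "age" not in cols or "height" not in cols:
        raise PanelFormatError("height table needs 'age' and 'height' columns")
    frame.columns = cols
    return {float(a): float(h) for a, h in zip(frame["age"], frame["height"])}
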