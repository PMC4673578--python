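"""Pluggable registry of creatinine- and cystatin C-based GFR-prediction equations.

The estimation strategy implemented by this package is deliberately
equation-agnostic: equations are *data*, described by an :class:`EquationSpec`
(functional form + parameter map + applicability guards) and held in an
:class:`EquationRegistry`.  Four functional forms are supported:

``power_law_cystatin``
    GFR = A · cysC^(−B), optionally times a pediatric multiplier below a
    configured age cutoff.  Works for adults and children.

``mdrd_like``
    GFR = c0 · (creatinine/88.4)^e1 · age^e2 · sex_coeff · population_coeff,
    the MDRD/CKD-EPI family shape (creatinine internally in mg/dL; the
    interface accepts μmol/L only, converted with exactly 88.4).

``height_over_creatinine``
    GFR = k · height / (creatinine/88.4), the pediatric Counahan–Barratt /
    Schwartz shape.

``piecewise_loglinear``
    ln GFR = X(creatinine, sex) + c_age·age + c_lnage·ln age with X piecewise
    linear in creatinine and ln creatinine per sex segment (the Lund–Malmö
    shape).  No default coefficients are shipped for this form; they must be
    supplied via config.

All forms are strictly decreasing in their marker, so each admits an exact
inverse — analytic where closed-form, by bracketing bisection otherwise —
used by the synthetic cohort generator.
"""

from __future__ import annotations

import enum
import io
import json
import math
import os
from dataclasses import dataclass, field, replace

import yaml
from scipy.optimize import brentq

from .errors import (
    ApplicabilityError,
    DomainError,
    DuplicateEquationError,
    InvalidEquationError,
    MarkerMissingError,
    UnknownEquationError,
)
from .types import GFREstimate, MarkerBasis, PatientRecord, Sex

#: Conversion constant between μmol/L and mg/dL plasma creatinine.
UMOL_PER_MGDL = 88.4

#: Default age (years) below which the pediatric cystatin multiplier applies.
DEFAULT_PEDIATRIC_CUTOFF = 14.0


class EquationForm(str, enum.Enum):
    power_law_cystatin = "power_law_cystatin"
    mdrd_like = "mdrd_like"
    height_over_creatinine = "height_over_creatinine"
    piecewise_loglinear = "piecewise_loglinear"


_FORM_BASIS = {
    EquationForm.power_law_cystatin: MarkerBasis.cystatin_c,
    EquationForm.mdrd_like: MarkerBasis.creatinine,
    EquationForm.height_over_creatinine: MarkerBasis.creatinine,
    EquationForm.piecewise_loglinear: MarkerBasis.creatinine,
}


@dataclass(frozen=True)
class EquationSpec:
    """One GFR-prediction equation: form, parameters and applicability guards.

    Parameters
    ----------
    equation_id
        Unique registry key.
    marker_basis
        ``creatinine`` or ``cystatin_c``; must match the form.
    form
        One of the four supported functional forms.
    params
        Named real-valued parameters of the form (see module docstring).
    age_range
        ``(min_years, max_years)`` applicability window, inclusive-lower /
        exclusive-upper except that the upper bound itself is accepted.
    required_fields
        PatientRecord field names that must be present for applicability.
    """

    equation_id: str
    marker_basis: MarkerBasis
    form: EquationForm
    params: dict = field(default_factory=dict)
    age_range: tuple[float, float] = (0.0, 120.0)
    required_fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_basis", MarkerBasis(self.marker_basis))
        object.__setattr__(self, "form", EquationForm(self.form))
        object.__setattr__(self, "age_range", tuple(float(a) for a in self.age_range))
        object.__setattr__(self, "required_fields", tuple(self.required_fields))
        self._validate()

    def _validate(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise InvalidEquationError(
                f"{self.equation_id}: age_range min must be < max, got {self.age_range}"
            )
        if _FORM_BASIS[self.form] is not self.marker_basis:
            raise InvalidEquationError(
                f"{self.equation_id}: form {self.form.value} requires marker_basis "
                f"{_FORM_BASIS[self.form].value}"
            )
        for name, value in self.params.items():
            if name == "segments":
                continue
            if name in ("population", "sex"):
                continue
            if not math.isfinite(float(value)):
                raise InvalidEquationError(
                    f"{self.equation_id}: parameter {name} is not finite"
                )
        if self.form is EquationForm.power_law_cystatin:
            if self.params.get("A", 0.0) <= 0 or self.params.get("B", 0.0) <= 0:
                raise InvalidEquationError(
                    f"{self.equation_id}: power_law_cystatin requires A > 0 and B > 0"
                )
        if self.form is EquationForm.piecewise_loglinear:
            segments = self.params.get("segments")
            if not segments:
                raise InvalidEquationError(
                    f"{self.equation_id}: piecewise_loglinear requires a non-empty "
                    "'segments' parameter (none are shipped by default)"
                )


def applicable(spec: EquationSpec, patient: PatientRecord) -> bool:
    """True iff the patient's age is inside ``spec.age_range`` and every
    required field is present.

    The lower age bound is inclusive, the upper bound exclusive; the exact
    upper endpoint is additionally accepted so a window like (18, 120) covers
    a 120-year-old.
    """
    lo, hi = spec.age_range
    if not (lo <= patient.age < hi or patient.age == hi):
        return False
    for name in spec.required_fields:
        if getattr(patient, name, None) is None:
            return False
    return True


def _require_applicable(spec: EquationSpec, patient: PatientRecord) -> None:
    lo, hi = spec.age_range
    if not (lo <= patient.age < hi or patient.age == hi):
        raise ApplicabilityError(
            f"equation {spec.equation_id!r}: patient age {patient.age} outside "
            f"age_range [{lo}, {hi})"
        )
    for name in spec.required_fields:
        if getattr(patient, name, None) is None:
            raise MarkerMissingError(
                f"equation {spec.equation_id!r}: required field {name!r} missing "
                f"for patient {patient.patient_id!r}"
            )


# ---------------------------------------------------------------------------
# Forward evaluation
# ---------------------------------------------------------------------------


def _power_law_value(spec: EquationSpec, cystatin_c: float, age: float) -> float:
    p = spec.params
    value = p["A"] * cystatin_c ** (-p["B"])
    mult = p.get("pediatric_multiplier")
    if mult is not None:
        cutoff = p.get("pediatric_age_cutoff", DEFAULT_PEDIATRIC_CUTOFF)
        if age < cutoff:  # strict comparison: a 14-year-old is adult-scaled
            value *= mult
    return value


def _mdrd_coeffs(spec: EquationSpec, patient: PatientRecord) -> float:
    """Multiplicative sex and population coefficients for an mdrd_like spec."""
    p = spec.params
    coeff = 1.0
    if patient.sex is Sex.female:
        coeff *= p.get("female_coeff", 1.0)
    pop = p.get("population")
    if pop is not None and patient.population == pop:
        coeff *= p.get("population_coeff", 1.0)
    return coeff


def _mdrd_value(spec: EquationSpec, creatinine: float, patient: PatientRecord) -> float:
    p = spec.params
    crea_mgdl = creatinine / UMOL_PER_MGDL
    return (
        p["c0"]
        * crea_mgdl ** p["e1"]
        * patient.age ** p["e2"]
        * _mdrd_coeffs(spec, patient)
    )


def _height_value(spec: EquationSpec, creatinine: float, patient: PatientRecord) -> float:
    crea_mgdl = creatinine / UMOL_PER_MGDL
    return spec.params["k"] * patient.height / crea_mgdl


def _piecewise_segment(spec: EquationSpec, creatinine: float, sex: Sex) -> dict:
    for seg in spec.params["segments"]:
        seg_sex = seg.get("sex", "any")
        if seg_sex not in ("any", sex.value):
            continue
        lo = seg.get("crea_min", 0.0)
        hi = seg.get("crea_max", math.inf)
        if lo <= creatinine < hi:
            return seg
    raise DomainError(
        f"equation {spec.equation_id!r}: no segment covers creatinine "
        f"{creatinine} μmol/L for sex {sex.value!r}"
    )


def _piecewise_value(
    spec: EquationSpec, creatinine: float, patient: PatientRecord
) -> float:
    p = spec.params
    seg = _piecewise_segment(spec, creatinine, patient.sex)
    log_gfr = (
        seg.get("intercept", 0.0)
        + seg.get("crea_coeff", 0.0) * creatinine
        + seg.get("log_crea_coeff", 0.0) * math.log(creatinine)
        + p.get("age_coeff", 0.0) * patient.age
        + p.get("log_age_coeff", 0.0) * math.log(patient.age)
    )
    return math.exp(log_gfr)


def _evaluate(spec: EquationSpec, marker: float, patient: PatientRecord) -> float:
    if spec.form is EquationForm.power_law_cystatin:
        return _power_law_value(spec, marker, patient.age)
    if spec.form is EquationForm.mdrd_like:
        return _mdrd_value(spec, marker, patient)
    if spec.form is EquationForm.height_over_creatinine:
        return _height_value(spec, marker, patient)
    return _piecewise_value(spec, marker, patient)


def egfr_cystatin(patient: PatientRecord, spec: EquationSpec) -> GFREstimate:
    """Relative eGFR from plasma cystatin C (mg/L)."""
    if spec.marker_basis is not MarkerBasis.cystatin_c:
        raise InvalidEquationError(
            f"equation {spec.equation_id!r} is not cystatin C-based"
        )
    if patient.cystatin_c is None:
        raise MarkerMissingError(
            f"patient {patient.patient_id!r} has no cystatin C value"
        )
    _require_applicable(spec, patient)
    value = _evaluate(spec, patient.cystatin_c, patient)
    return GFREstimate(value, MarkerBasis.cystatin_c, spec.equation_id)


def egfr_creatinine(patient: PatientRecord, spec: EquationSpec) -> GFREstimate:
    """Relative eGFR from plasma creatinine (μmol/L) and anthropometric data."""
    if spec.marker_basis is not MarkerBasis.creatinine:
        raise InvalidEquationError(
            f"equation {spec.equation_id!r} is not creatinine-based"
        )
    if patient.creatinine is None:
        raise MarkerMissingError(
            f"patient {patient.patient_id!r} has no creatinine value"
        )
    _require_applicable(spec, patient)
    value = _evaluate(spec, patient.creatinine, patient)
    return GFREstimate(value, MarkerBasis.creatinine, spec.equation_id)


def estimate(patient: PatientRecord, spec: EquationSpec) -> GFREstimate:
    """Dispatch to :func:`egfr_cystatin` or :func:`egfr_creatinine` by basis."""
    if spec.marker_basis is MarkerBasis.cystatin_c:
        return egfr_cystatin(patient, spec)
    return egfr_creatinine(patient, spec)


# ---------------------------------------------------------------------------
# Exact inversion (marker level from target GFR)
# ---------------------------------------------------------------------------


def invert_equation(
    target_gfr: float, patient: PatientRecord, spec: EquationSpec
) -> float:
    """Marker level (μmol/L creatinine or mg/L cystatin C) whose forward
    evaluation reproduces ``target_gfr``.

    Analytic for the closed-form families; bracketed root finding for the
    piecewise form.  Round-trips to within 1e−9 relative error.
    """
    if not (math.isfinite(target_gfr) and target_gfr > 0):
        raise DomainError(f"target_gfr must be > 0, got {target_gfr!r}")
    p = spec.params
    if spec.form is EquationForm.power_law_cystatin:
        a = p["A"]
        mult = p.get("pediatric_multiplier")
        if mult is not None and patient.age < p.get(
            "pediatric_age_cutoff", DEFAULT_PEDIATRIC_CUTOFF
        ):
            a *= mult
        return (target_gfr / a) ** (-1.0 / p["B"])
    if spec.form is EquationForm.mdrd_like:
        base = p["c0"] * patient.age ** p["e2"] * _mdrd_coeffs(spec, patient)
        return UMOL_PER_MGDL * (target_gfr / base) ** (1.0 / p["e1"])
    if spec.form is EquationForm.height_over_creatinine:
        if patient.height is None:
            raise MarkerMissingError(
                f"equation {spec.equation_id!r}: height required for inversion"
            )
        return UMOL_PER_MGDL * p["k"] * patient.height / target_gfr

    def objective(log_crea: float) -> float:
        return math.log(_piecewise_value(spec, math.exp(log_crea), patient)) - math.log(
            target_gfr
        )

    lo, hi = math.log(1e-2), math.log(1e5)
    if objective(lo) * objective(hi) > 0:
        raise DomainError(
            f"equation {spec.equation_id!r}: target GFR {target_gfr} not bracketed "
            "over creatinine in [0.01, 100000] μmol/L"
        )
    return math.exp(brentq(objective, lo, hi, xtol=1e-14, rtol=1e-15))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


class EquationRegistry:
    """Ordered, write-once mapping from equation id to :class:`EquationSpec`."""

    def __init__(self) -> None:
        self._specs: dict[str, EquationSpec] = {}

    def register(self, spec: EquationSpec) -> "EquationRegistry":
        if spec.equation_id in self._specs:
            raise DuplicateEquationError(
                f"equation id {spec.equation_id!r} is already registered"
            )
        self._specs[spec.equation_id] = spec
        return self

    def get(self, equation_id: str) -> EquationSpec:
        try:
            return self._specs[equation_id]
        except KeyError:
            raise UnknownEquationError(
                f"no equation registered under id {equation_id!r}"
            ) from None

    def __contains__(self, equation_id: str) -> bool:
        return equation_id in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def ids(self) -> list[str]:
        return list(self._specs)

    # -- config round-trip --------------------------------------------------

    def to_config(self) -> list[dict]:
        """Serialisable list of equation records with canonical key order."""
        records = []
        for spec in self:
            records.append(
                {
                    "age_range": [spec.age_range[0], spec.age_range[1]],
                    "equation_id": spec.equation_id,
                    "form": spec.form.value,
                    "marker_basis": spec.marker_basis.value,
                    "params": _canonical(spec.params),
                    "required_fields": list(spec.required_fields),
                }
            )
        return records

    @classmethod
    def from_config(cls, records: list[dict]) -> "EquationRegistry":
        registry = cls()
        for rec in records:
            registry.register(
                EquationSpec(
                    equation_id=rec["equation_id"],
                    marker_basis=rec["marker_basis"],
                    form=rec["form"],
                    params=rec.get("params", {}),
                    age_range=tuple(rec.get("age_range", (0.0, 120.0))),
                    required_fields=tuple(rec.get("required_fields", ())),
                )
            )
        return registry

    def dump(self, path_or_stream) -> None:
        """Write the registry as YAML (or JSON for ``.json`` paths).

        Dumping is canonical (sorted keys), so load → dump reproduces the
        file bit-identically.
        """
        records = self.to_config()
        if isinstance(path_or_stream, (str, os.PathLike)):
            path = os.fspath(path_or_stream)
            with open(path, "w", encoding="utf-8") as fh:
                _dump_records(records, fh, as_json=path.endswith(".json"))
        else:
            _dump_records(records, path_or_stream, as_json=False)

    @classmethod
    def load(cls, path_or_stream) -> "EquationRegistry":
        """Read a registry config from a YAML or JSON file (or stream)."""
        if isinstance(path_or_stream, (str, os.PathLike)):
            with open(os.fspath(path_or_stream), encoding="utf-8") as fh:
                records = yaml.safe_load(fh)
        else:
            records = yaml.safe_load(path_or_stream)
        return cls.from_config(records)


def _canonical(obj):
    if isinstance(obj, dict):
        return {k: _canonical(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def _dump_records(records: list[dict], stream, as_json: bool) -> None:
    if as_json:
        json.dump(records, stream, indent=2, sort_keys=True)
        stream.write("\n")
    else:
        yaml.safe_dump(records, stream, sort_keys=True, default_flow_style=False)


def register_equation(spec: EquationSpec, registry: EquationRegistry) -> EquationRegistry:
    """Functional alias for :meth:`EquationRegistry.register`."""
    return registry.register(spec)


def default_registry() -> EquationRegistry:
    """Registry pre-loaded with the shipped default equations.

    * ``cystatin_power`` — adult/pediatric cystatin C power law
      (A = 84.69, B = 1.680; ×1.384 below age 14).
    * ``mdrd`` — IDMS-traceable MDRD study equation
      (175, −1.154, −0.203; female ×0.742; black ×1.212), adults only.
    * ``mdrd_japanese`` — the same shape with the Japanese population
      coefficient 0.763.
    * ``counahan_barratt`` — pediatric height/creatinine equation (k = 0.43,
      creatinine internally in mg/dL), ages 1–18.

    Coefficients are registry data, fully overridable via config files.
    """
    registry = EquationRegistry()
    registry.register(
        EquationSpec(
            equation_id="cystatin_power",
            marker_basis=MarkerBasis.cystatin_c,
            form=EquationForm.power_law_cystatin,
            params={
                "A": 84.69,
                "B": 1.680,
                "pediatric_multiplier": 1.384,
                "pediatric_age_cutoff": 14.0,
            },
            age_range=(1.0, 120.0),
            required_fields=("cystatin_c",),
        )
    )
    mdrd = EquationSpec(
        equation_id="mdrd",
        marker_basis=MarkerBasis.creatinine,
        form=EquationForm.mdrd_like,
        params={
            "c0": 175.0,
            "e1": -1.154,
            "e2": -0.203,
            "female_coeff": 0.742,
            "population": "black",
            "population_coeff": 1.212,
        },
        age_range=(18.0, 120.0),
        required_fields=("creatinine",),
    )
    registry.register(mdrd)
    registry.register(
        replace(
            mdrd,
            equation_id="mdrd_japanese",
            params={
                **mdrd.params,
                "population": "japanese",
                "population_coeff": 0.763,
            },
        )
    )
    registry.register(
        EquationSpec(
            equation_id="counahan_barratt",
            marker_basis=MarkerBasis.creatinine,
            form=EquationForm.height_over_creatinine,
            params={"k": 0.43},
            age_range=(1.0, 18.0),
            required_fields=("creatinine", "height"),
        )
    )
    return registry


def dumps_config(registry: EquationRegistry) -> str:
    """Registry config as a canonical YAML string."""
    buf = io.StringIO()
    registry.dump(buf)
    return buf.getvalue()
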