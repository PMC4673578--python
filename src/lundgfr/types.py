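"""Core domain types: patients, clinical flags and GFR estimates.

Units are fixed at the interface and never inferred:

* plasma creatinine — μmol/L
* plasma cystatin C — mg/L
* relative GFR — mL/min/1.73 m²
* height — cm, weight — kg, age — years
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import DomainError


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class ClinicalFlag(str, enum.Enum):
    """Clinical-context flags consulted when the two estimates disagree.

    ``MUSCLE_MASS_LOW``/``MUSCLE_MASS_HIGH`` invalidate the creatinine-based
    estimate (creatinine production tracks muscle mass);
    ``GLUCOCORTICOID_MODERATE_HIGH_DOSE`` invalidates the cystatin C-based
    estimate (glucocorticoids increase cystatin C synthesis);
    ``MUSCLE_MASS_CHANGED`` invalidates a creatinine monitoring anchor.
    """

    MUSCLE_MASS_LOW = "MUSCLE_MASS_LOW"
    MUSCLE_MASS_HIGH = "MUSCLE_MASS_HIGH"
    GLUCOCORTICOID_MODERATE_HIGH_DOSE = "GLUCOCORTICOID_MODERATE_HIGH_DOSE"
    MUSCLE_MASS_CHANGED = "MUSCLE_MASS_CHANGED"


#: Flags that make the creatinine-based estimate unreliable.
CREATININE_INVALIDATING = frozenset(
    {ClinicalFlag.MUSCLE_MASS_LOW, ClinicalFlag.MUSCLE_MASS_HIGH}
)
#: Flags that make the cystatin C-based estimate unreliable.
CYSTATIN_INVALIDATING = frozenset({ClinicalFlag.GLUCOCORTICOID_MODERATE_HIGH_DOSE})


class MarkerBasis(str, enum.Enum):
    creatinine = "creatinine"
    cystatin_c = "cystatin_c"
    combined = "combined"


def _check_positive(name: str, value: float | None) -> None:
    if value is not None and not (math.isfinite(value) and value > 0):
        raise DomainError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, plasma marker levels and clinical flags.

    Optional fields left as ``None`` never default silently: an equation that
    requires them is simply not applicable to the patient.
    """

    patient_id: str
    age: float
    sex: Sex
    height: float | None = None
    weight: float | None = None
    population: str | None = None
    creatinine: float | None = None
    cystatin_c: float | None = None
    flags: frozenset[ClinicalFlag] = field(default_factory=frozenset)
    measured_gfr: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(
            self, "flags", frozenset(ClinicalFlag(f) for f in self.flags)
        )
        _check_positive("age", self.age)
        if self.age is None:
            raise DomainError("age is required")
        for name in ("height", "weight", "creatinine", "cystatin_c", "measured_gfr"):
            _check_positive(name, getattr(self, name))
        if (
            ClinicalFlag.MUSCLE_MASS_LOW in self.flags
            and ClinicalFlag.MUSCLE_MASS_HIGH in self.flags
        ):
            raise DomainError(
                "MUSCLE_MASS_LOW and MUSCLE_MASS_HIGH are mutually exclusive"
            )


@dataclass(frozen=True)
class GFREstimate:
    """A relative GFR estimate (mL/min/1.73 m²) with its provenance.

    ``equation_id`` is ``"mean"`` for the combined (arithmetic-mean) estimate.
    """

    value: float
    marker_basis: MarkerBasis
    equation_id: str
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_basis", MarkerBasis(self.marker_basis))
        object.__setattr__(self, "notes", tuple(self.notes))
        if not (math.isfinite(self.value) and self.value >= 0):
            raise DomainError(
                f"GFR estimate must be finite and >= 0, got {self.value!r}"
            )
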