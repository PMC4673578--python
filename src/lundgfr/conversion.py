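"""Body-surface-area computation and relative ↔ absolute GFR conversion.

Relative GFR is normalised to a body surface area of 1.73 m²; absolute GFR
(mL/min), needed e.g. for dosing of renally cleared drugs, is recovered as
``gfr_rel × BSA / 1.73``.  The DuBois–DuBois formula is the default BSA
estimate; alternatives are pluggable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import DomainError, UnknownFormulaError

#: Normalisation constant of relative GFR (m²), exactly as in its unit.
REFERENCE_BSA = 1.73


def _dubois(height: float, weight: float) -> float:
    return 0.007184 * height**0.725 * weight**0.425


def _mosteller(height: float, weight: float) -> float:
    return math.sqrt(height * weight / 3600.0)


_BSA_FORMULAS: dict[str, Callable[[float, float], float]] = {
    "dubois": _dubois,
    "mosteller": _mosteller,
}


@dataclass(frozen=True)
class BodySurfaceArea:
    value: float  # m²
    formula_id: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise DomainError(f"BSA must be positive and finite, got {self.value!r}")


def register_bsa_formula(
    formula_id: str, func: Callable[[float, float], float]
) -> None:
    """Register a BSA formula ``func(height_cm, weight_kg) -> m²``."""
    _BSA_FORMULAS[formula_id] = func


def bsa(height: float, weight: float, formula_id: str = "dubois") -> BodySurfaceArea:
    """Body surface area (m²) from height (cm) and weight (kg)."""
    if not (height > 0 and weight > 0):
        raise DomainError(
            f"height and weight must be > 0, got height={height!r}, weight={weight!r}"
        )
    try:
        func = _BSA_FORMULAS[formula_id]
    except KeyError:
        raise UnknownFormulaError(
            f"no BSA formula registered under id {formula_id!r}; "
            f"known: {sorted(_BSA_FORMULAS)}"
        ) from None
    return BodySurfaceArea(func(height, weight), formula_id)


def relative_to_absolute(gfr_rel: float, body_surface: BodySurfaceArea | float) -> float:
    """Absolute GFR (mL/min) from relative GFR (mL/min/1.73 m²)."""
    area = body_surface.value if isinstance(body_surface, BodySurfaceArea) else body_surface
    if not area > 0:
        raise DomainError(f"BSA must be > 0, got {area!r}")
    if gfr_rel < 0:
        raise DomainError(f"gfr_rel must be >= 0, got {gfr_rel!r}")
    return gfr_rel * area / REFERENCE_BSA


def absolute_to_relative(gfr_abs: float, body_surface: BodySurfaceArea | float) -> float:
    """Relative GFR (mL/min/1.73 m²) from absolute GFR (mL/min)."""
    area = body_surface.value if isinstance(body_surface, BodySurfaceArea) else body_surface
    if not area > 0:
        raise DomainError(f"BSA must be > 0, got {area!r}")
    if gfr_abs < 0:
        raise DomainError(f"gfr_abs must be >= 0, got {gfr_abs!r}")
    return gfr_abs * REFERENCE_BSA / area
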