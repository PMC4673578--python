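"""The two-marker GFR decision engine with internal quality check.

The strategy estimates relative GFR twice — once from cystatin C, once from
creatinine — and compares the two.  Agreement within a specified relative
limit validates both, and their arithmetic mean is reported.  On
disagreement the clinical context is consulted: a flag that invalidates one
marker routes the decision to the other marker's estimate alone; without an
explanation (or with both markers compromised) an invasive gold-standard
measurement is required.  A concordant decision additionally anchors the
patient's creatinine to a trusted GFR value, so follow-up can be monitored
from creatinine alone until muscle mass changes.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

from .equations import EquationRegistry, _evaluate, egfr_creatinine, egfr_cystatin
from .errors import AnchorError, DomainError, ReevaluationRequiredError
from .types import (
    CREATININE_INVALIDATING,
    CYSTATIN_INVALIDATING,
    ClinicalFlag,
    GFREstimate,
    MarkerBasis,
    PatientRecord,
    Sex,
)


class Route(str, enum.Enum):
    USE_MEAN = "USE_MEAN"
    USE_CYSTATIN = "USE_CYSTATIN"
    USE_CREATININE = "USE_CREATININE"
    GOLD_STANDARD_REQUIRED = "GOLD_STANDARD_REQUIRED"


@dataclass(frozen=True)
class ConcordancePolicy:
    """Agreement limits for the internal quality check.

    The relative difference |a−b| / mean(a, b) of the two estimates must not
    exceed the active limit.  Dosing of medication with potential adverse
    effects demands tighter agreement than general GFR evaluation, so the
    dosing limit must not exceed the general one.
    """

    context: str = "general"
    relative_limit_general: float = 0.30
    relative_limit_dosing: float = 0.10

    def __post_init__(self) -> None:
        if self.context not in ("general", "dosing"):
            raise DomainError(f"unknown policy context {self.context!r}")
        for name in ("relative_limit_general", "relative_limit_dosing"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DomainError(f"{name} must be in (0, 1), got {v!r}")
        if self.relative_limit_dosing > self.relative_limit_general:
            raise DomainError("dosing limit must not exceed the general limit")

    @property
    def active_limit(self) -> float:
        if self.context == "dosing":
            return self.relative_limit_dosing
        return self.relative_limit_general


@dataclass(frozen=True)
class LundDecision:
    """Outcome of the two-marker strategy for one patient."""

    route: Route
    e_cystatin: GFREstimate
    e_creatinine: GFREstimate
    relative_difference: float
    final_estimate: GFREstimate | None = None
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        present = self.final_estimate is not None
        if present == (self.route is Route.GOLD_STANDARD_REQUIRED):
            raise DomainError(
                "final_estimate must be present iff route != GOLD_STANDARD_REQUIRED"
            )

    def to_dict(self, patient_id: str | None = None) -> dict:
        """JSON-ready report with deterministic field order."""
        out: dict = {}
        if patient_id is not None:
            out["patient_id"] = patient_id
        out["route"] = self.route.value
        out["egfr_cystatin"] = self.e_cystatin.value
        out["egfr_creatinine"] = self.e_creatinine.value
        out["relative_difference"] = self.relative_difference
        out["final_estimate"] = (
            None if self.final_estimate is None else self.final_estimate.value
        )
        out["final_basis"] = (
            None
            if self.final_estimate is None
            else self.final_estimate.marker_basis.value
        )
        out["rationale"] = list(self.rationale)
        return out

    def to_json(self, patient_id: str | None = None) -> str:
        return json.dumps(self.to_dict(patient_id))


def _value(e) -> float:
    return e.value if isinstance(e, GFREstimate) else float(e)


def check_concordance(
    e_cys, e_crea, policy: ConcordancePolicy
) -> tuple[bool, float]:
    """Internal quality check: do the two estimates agree within the limit?

    Returns ``(concordant, relative_difference)`` where the relative
    difference is |a−b| divided by the pair mean — symmetric in its
    arguments and dimensionless.
    """
    a, b = _value(e_cys), _value(e_crea)
    if a <= 0 or b <= 0:
        raise DomainError(f"estimates must be > 0 for concordance, got {a}, {b}")
    rel = abs(a - b) / ((a + b) / 2.0)
    return rel <= policy.active_limit, rel


def combine_mean(e_cys, e_crea) -> GFREstimate:
    """Arithmetic mean of the two single-marker estimates."""
    a, b = _value(e_cys), _value(e_crea)
    if a < 0 or b < 0:
        raise DomainError("estimates must be >= 0")
    return GFREstimate((a + b) / 2.0, MarkerBasis.combined, "mean")


def resolve_discordance(flags: frozenset[ClinicalFlag] | set) -> Route:
    """Arbitration by clinical context when the two estimates disagree.

    Abnormal muscle mass invalidates the creatinine estimate; moderate/high
    glucocorticoid doses invalidate the cystatin C estimate.  With no
    explanation — or with both markers compromised — the discrepancy is
    unexplained and an invasive gold-standard measurement is required.
    """
    flags = frozenset(flags)
    crea_bad = bool(flags & CREATININE_INVALIDATING)
    cys_bad = bool(flags & CYSTATIN_INVALIDATING)
    if crea_bad and not cys_bad:
        return Route.USE_CYSTATIN
    if cys_bad and not crea_bad:
        return Route.USE_CREATININE
    return Route.GOLD_STANDARD_REQUIRED


def lund_decide(
    patient: PatientRecord,
    registry: EquationRegistry,
    cys_id: str,
    crea_id: str,
    policy: ConcordancePolicy | None = None,
    strict_flags: bool = False,
) -> LundDecision:
    """Run the full two-marker strategy for one patient.

    Flags are consulted only on discordance (concordance is treated as
    self-validating); ``strict_flags=True`` lets recorded flags veto the
    mean even when the estimates agree.
    """
    policy = policy or ConcordancePolicy()
    e_cys = egfr_cystatin(patient, registry.get(cys_id))
    e_crea = egfr_creatinine(patient, registry.get(crea_id))
    concordant, rel = check_concordance(e_cys, e_crea, policy)
    rationale = [
        f"limit={policy.active_limit:g} ({policy.context})",
        f"relative_difference={rel:.6g}",
    ]

    if concordant and not (strict_flags and patient.flags):
        rationale.append("concordant: arithmetic mean of the two estimates")
        return LundDecision(
            Route.USE_MEAN, e_cys, e_crea, rel, combine_mean(e_cys, e_crea),
            tuple(rationale),
        )

    if concordant:
        rationale.append("concordant but strict_flags set: flags consulted")
    else:
        rationale.append("discordant: clinical flags consulted")
    flags = sorted(f.value for f in patient.flags)
    rationale.append(f"flags={flags!r}")
    route = resolve_discordance(patient.flags)
    if route is Route.USE_CYSTATIN:
        rationale.append("creatinine estimate invalidated by abnormal muscle mass")
        final = e_cys
    elif route is Route.USE_CREATININE:
        rationale.append("cystatin C estimate invalidated by glucocorticoid treatment")
        final = e_crea
    else:
        rationale.append(
            "unexplained discrepancy: invasive gold-standard measurement required"
        )
        final = None
    return LundDecision(route, e_cys, e_crea, rel, final, tuple(rationale))


# ---------------------------------------------------------------------------
# Creatinine-anchored monitoring
# ---------------------------------------------------------------------------


@dataclass
class Anchor:
    """A trusted (creatinine, GFR) pair for creatinine-only follow-up.

    Set only after a concordant decision, which reliably connects the
    patient's creatinine level to a GFR value.  Follow-up estimates scale
    the anchored GFR by the anchored creatinine equation's own dependence on
    creatinine and age, keeping sex and population fixed.
    """

    creatinine_ref: float
    gfr_ref: float
    equation_id: str
    age_ref: float
    sex: Sex
    population: str | None = None
    height: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.creatinine_ref) and self.creatinine_ref > 0):
            raise DomainError("creatinine_ref must be > 0")
        if not (math.isfinite(self.gfr_ref) and self.gfr_ref > 0):
            raise DomainError("gfr_ref must be > 0")


def make_anchor(
    decision: LundDecision, patient: PatientRecord, crea_id: str
) -> Anchor:
    """Anchor the patient's creatinine to the concordant GFR estimate.

    Only a USE_MEAN decision may be anchored: monitoring is permitted only
    after the internal quality check has validated both estimates.
    """
    if decision.route is not Route.USE_MEAN:
        raise AnchorError(
            f"monitoring anchor refused: decision route is {decision.route.value}, "
            "anchoring requires USE_MEAN (concordant estimates)"
        )
    if patient.creatinine is None:
        raise AnchorError("patient has no creatinine value to anchor")
    return Anchor(
        creatinine_ref=patient.creatinine,
        gfr_ref=decision.final_estimate.value,
        equation_id=crea_id,
        age_ref=patient.age,
        sex=patient.sex,
        population=patient.population,
        height=patient.height,
    )


def monitor(
    anchor: Anchor,
    new_creatinine: float,
    new_age: float,
    flags: frozenset[ClinicalFlag] | set,
    registry: EquationRegistry,
) -> GFREstimate:
    """Follow-up GFR estimate from creatinine alone, scaled off the anchor.

    value = gfr_ref × f(new_creatinine, new_age) / f(creatinine_ref, age_ref)
    where f is the anchored creatinine equation with the anchored sex,
    population and height.  A MUSCLE_MASS_CHANGED flag invalidates the
    anchor: the full two-marker strategy must be repeated.
    """
    flags = frozenset(ClinicalFlag(f) for f in flags)
    if ClinicalFlag.MUSCLE_MASS_CHANGED in flags:
        anchor.valid = False
    if not anchor.valid:
        raise ReevaluationRequiredError(
            "muscle mass changed since anchoring: repeat the two-marker strategy"
        )
    if not (math.isfinite(new_creatinine) and new_creatinine > 0):
        raise DomainError(f"new_creatinine must be > 0, got {new_creatinine!r}")
    spec = registry.get(anchor.equation_id)

    def f(creatinine: float, age: float) -> float:
        probe = PatientRecord(
            patient_id="<anchor>",
            age=age,
            sex=anchor.sex,
            population=anchor.population,
            height=anchor.height,
            creatinine=creatinine,
        )
        # Ratio scaling off the same equation: the age-range guard is not
        # re-applied, markers are.
        return _evaluate(spec, creatinine, probe)

    value = anchor.gfr_ref * f(new_creatinine, new_age) / f(
        anchor.creatinine_ref, anchor.age_ref
    )
    return GFREstimate(
        value,
        MarkerBasis.creatinine,
        anchor.equation_id,
        notes=(
            f"anchored at creatinine {anchor.creatinine_ref:g} umol/L, "
            f"GFR {anchor.gfr_ref:g} mL/min/1.73m2, age {anchor.age_ref:g}",
        ),
    )
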