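"""Seeded synthetic patient cohorts with known ground truth.

Each synthetic patient has a known true relative GFR and known confounder
state.  Marker levels are produced by *exact inversion* of the registered
prediction equations, then perturbed mechanistically:

* a multiplicative muscle-mass factor M acts on creatinine only (creatinine
  production tracks muscle mass; cystatin C is essentially independent of it);
* a multiplicative steroid factor G ≥ 1 acts on cystatin C only
  (glucocorticoids increase cystatin C synthesis);
* multiplicative lognormal assay noise acts on both markers;
* gold-standard measurements carry their own multiplicative lognormal
  imprecision — no reference method is error-free.

With all noise and confounders switched off, both single-marker estimates
reproduce the true GFR exactly, so every decision path and accuracy claim is
testable without external patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decision import ConcordancePolicy, Route, check_concordance, resolve_discordance
from .equations import EquationRegistry, _evaluate, invert_equation
from .errors import DomainError
from .types import ClinicalFlag, PatientRecord, Sex


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Noise magnitudes are coefficients of variation (CV, dimensionless
    fractions); multiplicative lognormal noise uses sd-log = ln(1 + CV)
    (a first-order approximation that keeps the median unbiased).

    ``muscle_abnormal_factor`` is the forced muscle factor for the abnormal
    subgroup (e.g. 0.5 for severe muscle loss, 2.0 for unusually high muscle
    mass); ``steroid_factor`` is the cystatin C inflation under
    moderate/high-dose glucocorticoid treatment.
    """

    n: int
    seed: int
    true_gfr_range: tuple[float, float] = (10.0, 120.0)
    age_range: tuple[float, float] = (18.0, 90.0)
    sex_ratio: float = 0.5  # fraction female
    sigma_muscle: float = 0.15  # sd-log of the baseline muscle factor
    p_muscle_abnormal: float = 0.0
    muscle_abnormal_factor: float = 0.5
    p_glucocorticoid: float = 0.0
    steroid_factor: float = 2.0
    cv_creatinine_assay: float = 0.05
    cv_cystatin_assay: float = 0.05
    cv_gold_standard: float = 0.10
    flags_observed: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        for name in ("true_gfr_range", "age_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise DomainError(f"{name} must be an ordered positive range")
        for name in (
            "sigma_muscle",
            "cv_creatinine_assay",
            "cv_cystatin_assay",
            "cv_gold_standard",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("sex_ratio", "p_muscle_abnormal", "p_glucocorticoid"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DomainError(f"{name} must be in [0, 1]")
        if self.steroid_factor < 1.0:
            raise DomainError("steroid_factor must be >= 1")
        if self.muscle_abnormal_factor <= 0:
            raise DomainError("muscle_abnormal_factor must be > 0")


@dataclass
class CohortTruth:
    """Per-patient ground truth for recovery testing."""

    true_gfr: np.ndarray
    muscle_factor: np.ndarray
    steroid_factor: np.ndarray
    flags_true: list[frozenset[ClinicalFlag]]
    expected_route: list[Route]
    measured_gfr: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.true_gfr)


def _sigma_log(cv: float) -> float:
    return math.log1p(cv)


def measure_gold_standard(true_gfr, cv: float, rng: np.random.Generator):
    """Simulate a gold-standard GFR measurement with imprecision CV.

    Multiplicative lognormal error with mean-log 0 and sd-log ln(1 + cv);
    ``cv = 0`` returns the true value exactly.  Accepts scalars or arrays.
    """
    if cv < 0:
        raise DomainError(f"cv must be >= 0, got {cv!r}")
    arr = np.asarray(true_gfr, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("true_gfr must be > 0")
    if cv == 0:
        return true_gfr if np.isscalar(true_gfr) else arr.copy()
    noisy = arr * np.exp(rng.normal(0.0, _sigma_log(cv), size=arr.shape))
    return float(noisy) if np.isscalar(true_gfr) else noisy


def generate_cohort(
    config: CohortConfig,
    registry: EquationRegistry,
    cys_id: str,
    crea_id: str,
    policy: ConcordancePolicy | None = None,
) -> tuple[list[PatientRecord], CohortTruth]:
    """Generate a cohort of synthetic patients plus its ground truth.

    Marker levels are obtained by inverting the named equations at the true
    GFR and applying confounder factors and assay noise:

        creatinine_i = invert_crea(gfr_i) · M_i · ε_crea,i
        cystatin_i   = invert_cys(gfr_i)  · G_i · ε_cys,i

    Confounded patients carry the corresponding clinical flag; flags are
    recorded on the patient records only when ``config.flags_observed`` is
    true (the truth always retains them).  ``expected_route`` is the route
    the decision engine takes in the absence of assay noise, given the
    recorded flags.  Fully reproducible from ``config.seed``.
    """
    policy = policy or ConcordancePolicy()
    cys_spec = registry.get(cys_id)
    crea_spec = registry.get(crea_id)
    rng = np.random.default_rng(config.seed)
    n = config.n

    true_gfr = rng.uniform(*config.true_gfr_range, size=n)
    ages = rng.uniform(*config.age_range, size=n)
    is_female = rng.random(n) < config.sex_ratio
    heights = np.clip(rng.normal(0.0, 7.0, size=n) + np.where(is_female, 163.0, 176.0), 120.0, 220.0)
    weights = np.clip(rng.normal(0.0, 12.0, size=n) + np.where(is_female, 66.0, 80.0), 35.0, 200.0)

    muscle = (
        np.exp(rng.normal(0.0, config.sigma_muscle, size=n))
        if config.sigma_muscle > 0
        else np.ones(n)
    )
    abnormal = rng.random(n) < config.p_muscle_abnormal
    muscle = np.where(abnormal, config.muscle_abnormal_factor, muscle)
    treated = rng.random(n) < config.p_glucocorticoid
    steroid = np.where(treated, config.steroid_factor, 1.0)

    eps_crea = (
        np.exp(rng.normal(0.0, _sigma_log(config.cv_creatinine_assay), size=n))
        if config.cv_creatinine_assay > 0
        else np.ones(n)
    )
    eps_cys = (
        np.exp(rng.normal(0.0, _sigma_log(config.cv_cystatin_assay), size=n))
        if config.cv_cystatin_assay > 0
        else np.ones(n)
    )
    gold = measure_gold_standard(true_gfr, config.cv_gold_standard, rng)

    patients: list[PatientRecord] = []
    flags_true: list[frozenset[ClinicalFlag]] = []
    expected_route: list[Route] = []
    for i in range(n):
        sex = Sex.female if is_female[i] else Sex.male
        flags = set()
        if abnormal[i]:
            flags.add(
                ClinicalFlag.MUSCLE_MASS_LOW
                if config.muscle_abnormal_factor < 1.0
                else ClinicalFlag.MUSCLE_MASS_HIGH
            )
        if treated[i]:
            flags.add(ClinicalFlag.GLUCOCORTICOID_MODERATE_HIGH_DOSE)
        flags = frozenset(flags)
        demographics = PatientRecord(
            patient_id=f"S{i:06d}",
            age=float(ages[i]),
            sex=sex,
            height=float(heights[i]),
            weight=float(weights[i]),
        )
        crea_true = invert_equation(float(true_gfr[i]), demographics, crea_spec)
        cys_true = invert_equation(float(true_gfr[i]), demographics, cys_spec)
        crea_obs = crea_true * muscle[i] * eps_crea[i]
        cys_obs = cys_true * steroid[i] * eps_cys[i]
        recorded = flags if config.flags_observed else frozenset()
        patients.append(
            PatientRecord(
                patient_id=demographics.patient_id,
                age=demographics.age,
                sex=sex,
                height=demographics.height,
                weight=demographics.weight,
                creatinine=float(crea_obs),
                cystatin_c=float(cys_obs),
                flags=recorded,
                measured_gfr=float(gold[i]),
            )
        )
        flags_true.append(flags)

        # Expected (noise-free) route given the recorded flags.
        e_crea_clean = _evaluate(crea_spec, crea_true * muscle[i], patients[-1])
        e_cys_clean = _evaluate(cys_spec, cys_true * steroid[i], patients[-1])
        concordant, _ = check_concordance(e_cys_clean, e_crea_clean, policy)
        expected_route.append(
            Route.USE_MEAN if concordant else resolve_discordance(recorded)
        )

    truth = CohortTruth(
        true_gfr=true_gfr,
        muscle_factor=muscle,
        steroid_factor=steroid,
        flags_true=flags_true,
        expected_route=expected_route,
        measured_gfr=np.asarray(gold, dtype=float),
    )
    return patients, truth
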