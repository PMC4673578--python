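"""Accuracy metrics for GFR-estimator validation.

P30 — the percentage of estimates within ±30% of the reference (measured)
GFR — is the field's standard accuracy summary; P10 is its tighter analogue.
A value exactly on the boundary counts as within (the comparison is ≤),
which matters because published P30 figures are sensitive to this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


def _as_arrays(estimates, reference) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise DomainError(
            f"estimates and reference must be equal-length 1-d sequences, "
            f"got shapes {est.shape} and {ref.shape}"
        )
    if est.size == 0:
        raise DomainError("empty input")
    if np.any(ref <= 0):
        raise DomainError("reference values must all be > 0")
    return est, ref


def p_within(estimates, reference, fraction: float) -> float:
    """Percentage of estimates within ±``fraction`` of the reference.

    ``p_within(est, ref, 0.30)`` is the P30 statistic.  Boundary values
    count as within.
    """
    est, ref = _as_arrays(estimates, reference)
    if fraction < 0:
        raise DomainError(f"fraction must be >= 0, got {fraction!r}")
    within = np.abs(est - ref) <= fraction * ref
    return 100.0 * float(np.count_nonzero(within)) / est.size


@dataclass(frozen=True)
class AccuracyReport:
    """P30/P10 accuracy, median bias and median absolute relative error."""

    n: int
    p30: float
    p10: float
    median_bias: float
    median_absolute_relative_error: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p10 <= self.p30 <= 100.0):
            raise DomainError("require 0 <= p10 <= p30 <= 100")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p30": self.p30,
            "p10": self.p10,
            "median_bias": self.median_bias,
            "median_absolute_relative_error": self.median_absolute_relative_error,
        }


def accuracy_report(estimates, reference) -> AccuracyReport:
    """Summarise estimator accuracy against a (gold-standard) reference."""
    est, ref = _as_arrays(estimates, reference)
    rel_err = (est - ref) / ref
    return AccuracyReport(
        n=est.size,
        p30=p_within(est, ref, 0.30),
        p10=p_within(est, ref, 0.10),
        median_bias=float(np.median(est - ref)),
        median_absolute_relative_error=float(np.median(np.abs(rel_err))),
    )
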