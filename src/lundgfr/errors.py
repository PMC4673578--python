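"""Exception hierarchy for the GFR estimation toolkit.

All package errors derive from :class:`LundGFRError` so callers can catch one
base class; subclasses also derive from ``ValueError``/``KeyError`` where that
matches the failure mode.
"""


class LundGFRError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(LundGFRError, ValueError):
    """An input value is outside its mathematical/physiological domain."""


class InvalidEquationError(LundGFRError, ValueError):
    """An equation specification violates its invariants."""


class DuplicateEquationError(LundGFRError, ValueError):
    """Attempt to register an equation id that already exists."""


class UnknownEquationError(LundGFRError, KeyError):
    """Lookup of an equation id that is not registered."""


class UnknownFormulaError(LundGFRError, KeyError):
    """Lookup of a body-surface-area formula id that is not registered."""


class ApplicabilityError(LundGFRError, ValueError):
    """An equation was applied to a patient outside its applicability guards."""


class MarkerMissingError(LundGFRError, ValueError):
    """A required plasma marker (or anthropometric field) is absent."""


class AnchorError(LundGFRError, ValueError):
    """A monitoring anchor was requested or used in an invalid state."""


class ReevaluationRequiredError(AnchorError):
    """The anchored creatinine-GFR link is no longer trustworthy.

    Raised when muscle mass has changed since the anchor was set: the full
    two-marker strategy must be repeated before monitoring can resume.
    """


class PanelFormatError(LundGFRError, ValueError):
    """A patient panel file is malformed (missing column, bad cell, ...)."""
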