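"""Equation registry, forward evaluation, guards and exact inversion."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lundgfr import (
    EquationForm,
    EquationRegistry,
    EquationSpec,
    MarkerBasis,
    PatientRecord,
    applicable,
    egfr_creatinine,
    egfr_cystatin,
    estimate,
    invert_equation,
)
from lundgfr.errors import (
    ApplicabilityError,
    DuplicateEquationError,
    InvalidEquationError,
    MarkerMissingError,
    UnknownEquationError,
)

# A synthetic piecewise log-linear creatinine equation (coefficients invented
# for testing the form; no clinically validated piecewise coefficients ship
# with the package).  The upper segment's intercept is chosen so the two
# pieces join continuously at the 150 umol/L breakpoint.
import math

_BREAK = 150.0
_UPPER_INTERCEPT = 5.2 - 0.011 * _BREAK + 1.2 * math.log(_BREAK)
SYNTHETIC_PIECEWISE = EquationSpec(
    equation_id="piecewise_synthetic",
    marker_basis="creatinine",
    form="piecewise_loglinear",
    params={
        "age_coeff": -0.005,
        "log_age_coeff": 0.3,
        "segments": [
            {"sex": "any", "crea_min": 0.0, "crea_max": _BREAK,
             "intercept": 5.2, "crea_coeff": -0.011},
            {"sex": "any", "crea_min": _BREAK,
             "intercept": _UPPER_INTERCEPT, "log_crea_coeff": -1.2},
        ],
    },
    age_range=(1.0, 120.0),
    required_fields=("creatinine",),
)


class TestRegistry:
    def test_round_trip_lookup(self, registry):
        spec = registry.get("cystatin_power")
        assert spec.params["A"] == 84.69
        assert spec.params["B"] == 1.680

    def test_japanese_variant_retrievable_with_printed_coefficient(self, registry):
        spec = registry.get("mdrd_japanese")
        assert spec.params["population_coeff"] == 0.763
        assert spec.params["population"] == "japanese"

    def test_duplicate_id_rejected(self, registry):
        with pytest.raises(DuplicateEquationError, match="mdrd"):
            registry.register(registry.get("mdrd"))

    def test_unknown_id_rejected(self, registry):
        with pytest.raises(UnknownEquationError):
            registry.get("nope")

    def test_invalid_power_law_params_rejected(self):
        with pytest.raises(InvalidEquationError):
            EquationSpec(
                equation_id="bad",
                marker_basis="cystatin_c",
                form="power_law_cystatin",
                params={"A": -1.0, "B": 1.0},
            )

    def test_enumeration_preserves_registration_order(self, registry):
        assert registry.ids() == [
            "cystatin_power", "mdrd", "mdrd_japanese", "counahan_barratt",
        ]

    def test_config_dump_load_dump_is_bit_identical(self, registry):
        buf1 = io.StringIO()
        registry.dump(buf1)
        reloaded = EquationRegistry.load(io.StringIO(buf1.getvalue()))
        buf2 = io.StringIO()
        reloaded.dump(buf2)
        assert buf1.getvalue() == buf2.getvalue()
        assert reloaded.ids() == registry.ids()


class TestApplicability:
    def test_adult_equation_excludes_children(self, registry):
        child = PatientRecord("c", 10.0, "male", creatinine=40.0)
        assert not applicable(registry.get("mdrd"), child)

    def test_lower_age_bound_inclusive(self):
        spec = EquationSpec(
            equation_id="wide", marker_basis="cystatin_c",
            form="power_law_cystatin", params={"A": 80.0, "B": 1.5},
            age_range=(1.0, 120.0), required_fields=("cystatin_c",),
        )
        assert applicable(spec, PatientRecord("p", 1.0, "female", cystatin_c=1.0))

    def test_missing_required_field_inapplicable(self, registry):
        child = PatientRecord("c", 8.0, "female", creatinine=40.0)  # no height
        assert not applicable(registry.get("counahan_barratt"), child)

    def test_missing_marker_raises_named_error(self, registry, adult_female):
        no_cys = PatientRecord("p", 40.0, "female", creatinine=80.0)
        with pytest.raises(MarkerMissingError, match="cystatin"):
            egfr_cystatin(no_cys, registry.get("cystatin_power"))

    def test_out_of_range_age_raises_applicability_error(self, registry):
        child = PatientRecord("c", 10.0, "male", creatinine=40.0)
        with pytest.raises(ApplicabilityError, match="age"):
            egfr_creatinine(child, registry.get("mdrd"))


class TestForwardEvaluation:
    def test_cystatin_identity_point(self, registry):
        """At cystatin C = 1 mg/L the power law returns A (adult patient)."""
        p = PatientRecord("p", 40.0, "female", cystatin_c=1.0)
        assert egfr_cystatin(p, registry.get("cystatin_power")).value == pytest.approx(
            84.69
        )

    def test_cystatin_hand_computed_value(self, registry, adult_female):
        # 84.69 * 2^-1.680 = 26.43, hand-evaluated before implementation
        est = egfr_cystatin(adult_female, registry.get("cystatin_power"))
        assert est.value == pytest.approx(26.43, abs=0.01)
        assert est.marker_basis is MarkerBasis.cystatin_c

    def test_pediatric_multiplier_below_cutoff_only(self, registry):
        spec = registry.get("cystatin_power")
        child = PatientRecord("c", 13.9, "male", cystatin_c=1.0)
        adult = PatientRecord("a", 14.0, "male", cystatin_c=1.0)
        assert egfr_cystatin(child, spec).value == pytest.approx(84.69 * 1.384)
        assert egfr_cystatin(adult, spec).value == pytest.approx(84.69)

    def test_power_law_doubling_identity(self, registry):
        spec = registry.get("cystatin_power")
        a = egfr_cystatin(PatientRecord("p", 40, "male", cystatin_c=0.8), spec).value
        b = egfr_cystatin(PatientRecord("p", 40, "male", cystatin_c=1.6), spec).value
        assert a / b == pytest.approx(2.0**1.680, rel=1e-12)

    def test_mdrd_hand_computed_value(self, registry, adult_female):
        # 175 * (80/88.4)^-1.154 * 40^-0.203 * 0.742 = 68.9 (hand oracle)
        est = egfr_creatinine(adult_female, registry.get("mdrd"))
        assert est.value == pytest.approx(68.9, abs=0.05)

    def test_japanese_coefficient_is_exactly_multiplicative(self, registry):
        p = PatientRecord(
            "p", 40.0, "female", creatinine=80.0, population="japanese"
        )
        base = egfr_creatinine(p, registry.get("mdrd")).value
        jp = egfr_creatinine(p, registry.get("mdrd_japanese")).value
        assert jp / base == pytest.approx(0.763, rel=1e-12)

    def test_population_coefficient_applied_only_on_match(self, registry):
        general = PatientRecord("g", 50.0, "male", creatinine=100.0)
        black = PatientRecord("b", 50.0, "male", creatinine=100.0, population="black")
        spec = registry.get("mdrd")
        ratio = egfr_creatinine(black, spec).value / egfr_creatinine(general, spec).value
        assert ratio == pytest.approx(1.212, rel=1e-12)

    def test_female_coefficient_exactly_multiplicative(self, registry):
        f = PatientRecord("f", 50.0, "female", creatinine=100.0)
        m = PatientRecord("m", 50.0, "male", creatinine=100.0)
        spec = registry.get("mdrd")
        assert egfr_creatinine(f, spec).value / egfr_creatinine(m, spec).value == (
            pytest.approx(0.742, rel=1e-12)
        )

    def test_height_over_creatinine_ratio_identity(self, registry):
        # k * height = creatinine in mg/dL  =>  eGFR = 1
        spec = registry.get("counahan_barratt")
        height = 120.0
        crea_umol = 0.43 * height * 88.4
        child = PatientRecord("c", 8.0, "male", height=height, creatinine=crea_umol)
        assert egfr_creatinine(child, spec).value == pytest.approx(1.0, rel=1e-12)

    def test_piecewise_segment_selection_and_continuity_of_evaluation(self):
        p_low = PatientRecord("p", 40.0, "female", creatinine=100.0)
        p_high = PatientRecord("p", 40.0, "female", creatinine=300.0)
        low = estimate(p_low, SYNTHETIC_PIECEWISE).value
        high = estimate(p_high, SYNTHETIC_PIECEWISE).value
        assert low > high > 0

    @pytest.mark.parametrize(
        "equation_id", ["cystatin_power", "mdrd", "mdrd_japanese", "counahan_barratt"]
    )
    def test_strict_monotone_decreasing_in_marker(self, registry, equation_id):
        """Every registered equation falls strictly as its marker rises."""
        spec = registry.get(equation_id)
        age = 10.0 if equation_id == "counahan_barratt" else 40.0
        grid = np.linspace(0.05, 50.0, 1000) if (
            spec.marker_basis is MarkerBasis.cystatin_c
        ) else np.linspace(5.0, 2000.0, 1000)
        values = []
        for marker in grid:
            kwargs = {spec.marker_basis.value: float(marker)}
            p = PatientRecord("p", age, "female", height=140.0, **kwargs)
            values.append(estimate(p, spec).value)
        assert np.all(np.diff(values) < 0)

    def test_piecewise_monotone_decreasing_across_breakpoint(self):
        grid = np.linspace(5.0, 2000.0, 1000)
        vals = [
            estimate(
                PatientRecord("p", 40.0, "female", creatinine=float(c)),
                SYNTHETIC_PIECEWISE,
            ).value
            for c in grid
        ]
        assert np.all(np.diff(vals) < 0)


class TestInversion:
    @pytest.mark.parametrize(
        "equation_id", ["cystatin_power", "mdrd", "mdrd_japanese", "counahan_barratt"]
    )
    @pytest.mark.parametrize("target", list(range(5, 151, 5)))
    def test_forward_of_inverse_is_identity(self, registry, equation_id, target):
        """forward(invert(g)) = g to 1e-9 relative for all built-in equations."""
        spec = registry.get(equation_id)
        age = 10.0 if equation_id == "counahan_barratt" else 40.0
        p = PatientRecord("p", age, "female", height=140.0, population="japanese")
        marker = invert_equation(float(target), p, spec)
        probe = PatientRecord(
            "p", age, "female", height=140.0, population="japanese",
            **{spec.marker_basis.value: marker},
        )
        assert estimate(probe, spec).value == pytest.approx(target, rel=1e-9)

    def test_inverse_of_identity_point(self, registry):
        p = PatientRecord("p", 40.0, "female")
        assert invert_equation(84.69, p, registry.get("cystatin_power")) == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_round_trip_from_marker(self, registry, adult_male):
        spec = registry.get("mdrd")
        g = egfr_creatinine(adult_male, spec).value
        assert invert_equation(g, adult_male, spec) == pytest.approx(
            adult_male.creatinine, rel=1e-9
        )

    @pytest.mark.parametrize("target", [5.0, 20.0, 60.0, 120.0, 150.0])
    def test_piecewise_bisection_round_trip(self, target):
        p = PatientRecord("p", 40.0, "female")
        marker = invert_equation(target, p, SYNTHETIC_PIECEWISE)
        probe = PatientRecord("p", 40.0, "female", creatinine=marker)
        assert estimate(probe, SYNTHETIC_PIECEWISE).value == pytest.approx(
            target, rel=1e-9
        )

    def test_nonpositive_target_rejected(self, registry, adult_female):
        from lundgfr.errors import DomainError

        with pytest.raises(DomainError):
            invert_equation(0.0, adult_female, registry.get("mdrd"))

    @given(
        target=st.floats(5.0, 150.0),
        age=st.floats(18.0, 100.0),
        a=st.floats(40.0, 150.0),
        b=st.floats(0.5, 3.0),
    )
    def test_power_law_round_trip_property(self, target, age, a, b):
        spec = EquationSpec(
            equation_id="pl", marker_basis="cystatin_c",
            form="power_law_cystatin", params={"A": a, "B": b},
            age_range=(0.0, 120.0), required_fields=("cystatin_c",),
        )
        p = PatientRecord("p", age, "male")
        marker = invert_equation(target, p, spec)
        probe = PatientRecord("p", age, "male", cystatin_c=marker)
        assert estimate(probe, spec).value == pytest.approx(target, rel=1e-9)
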