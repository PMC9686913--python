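"""Structural model: clearance covariate law and the infusion solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vancopta.pk import (
    DosingRegimen,
    PopulationParameters,
    SubjectRealization,
    clearance_for_egfr,
    concentration,
    concentration_profile,
    one_compartment_concentration,
)

from _oracles import ode_concentrations


class TestClearanceCovariateModel:
    @pytest.mark.parametrize(
        "theta0, theta1, egfr, expected",
        [
            (5.2, 0.62, 144.0, 5.2),  # reference eGFR returns theta0
            (5.2, 0.0, 37.0, 5.2),  # zero exponent kills the covariate
            (5.2, 0.62, 120.3, 4.65137),  # hand-evaluated power law
        ],
    )
    def test_power_law(self, theta0, theta1, egfr, expected):
        pop = PopulationParameters(theta0_cl=theta0, theta1_cl=theta1)
        assert clearance_for_egfr(pop, egfr) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_egfr_rejected(self, pop):
        with pytest.raises(ValueError):
            clearance_for_egfr(pop, 0.0)
        with pytest.raises(ValueError):
            clearance_for_egfr(pop, -30.0)


class TestParameterValidation:
    def test_invalid_population_parameters(self):
        with pytest.raises(ValueError):
            PopulationParameters(v1=-1.0)
        with pytest.raises(ValueError):
            PopulationParameters(rho_v1_cl=1.2)

    def test_invalid_regimen(self):
        with pytest.raises(ValueError):
            DosingRegimen(1000.0, 12.0, 13.0, 4)  # Tinf > II
        with pytest.raises(ValueError):
            DosingRegimen(-1.0, 12.0, 2.0, 4)


class TestConcentration:
    def test_zero_before_and_at_first_dose(self, regimen_1g_q12h, typical_subject):
        assert concentration(0.0, regimen_1g_q12h, typical_subject) == 0.0

    def test_matches_ode_oracle(self, regimen_1g_q12h, typical_subject):
        """Closed-form biexponential superposition agrees with numerical
        integration of the two-compartment system to 1e-6 relative."""
        grid = np.linspace(0.25, 96.0, 120)
        oracle = ode_concentrations(grid, regimen_1g_q12h, typical_subject)
        closed = concentration_profile(grid, regimen_1g_q12h, typical_subject)
        assert np.max(np.abs(closed - oracle) / np.abs(oracle)) < 1e-6

    def test_matches_ode_oracle_atypical_subject(self):
        subj = SubjectRealization(cl=9.3, q=1.7, v1=40.0, v2=11.0, egfr=100.0)
        regimen = DosingRegimen(750.0, 8.0, 4.0, 12)
        grid = np.linspace(0.5, 90.0, 80)
        oracle = ode_concentrations(grid, regimen, subj)
        closed = concentration_profile(grid, regimen, subj)
        assert np.max(np.abs(closed - oracle) / np.abs(oracle)) < 1e-6

    def test_one_compartment_limit(self, regimen_1g_q12h):
        """As Q -> 0 the model collapses to the one-compartment solution."""
        subj = SubjectRealization(cl=5.2, q=1e-9, v1=21.22, v2=28.28, egfr=144.0)
        grid = np.linspace(0.5, 48.0, 60)
        two = concentration_profile(grid, regimen_1g_q12h, subj)
        one = one_compartment_concentration(grid, regimen_1g_q12h, 5.2, 21.22)
        assert np.allclose(two, one, rtol=1e-6)

    def test_superposition(self, typical_subject):
        """Multi-dose profile is the sum of time-shifted single doses."""
        multi = DosingRegimen(1000.0, 12.0, 2.0, 5)
        grid = np.linspace(0.0, 72.0, 289)
        total = concentration_profile(grid, multi, typical_subject)
        acc = np.zeros_like(grid)
        for k in range(5):
            single = DosingRegimen(1000.0, 12.0, 2.0, 1, first_dose_time=12.0 * k)
            acc += concentration_profile(grid, single, typical_subject)
        assert np.allclose(total, acc, rtol=1e-10, atol=1e-12)

    def test_continuity_at_infusion_stop(self, regimen_1g_q12h, typical_subject):
        eps = 1e-9
        left = concentration(2.0 - eps, regimen_1g_q12h, typical_subject)
        right = concentration(2.0 + eps, regimen_1g_q12h, typical_subject)
        assert left == pytest.approx(right, rel=1e-6)

    def test_steady_state_periodicity(self, typical_subject):
        """Far beyond the terminal half-life, C(t) ~= C(t + II)."""
        regimen = DosingRegimen(1000.0, 12.0, 2.0, 30)
        t = np.array([300.0, 302.0, 306.0, 311.0])
        a = concentration_profile(t, regimen, typical_subject)
        b = concentration_profile(t + 12.0, regimen, typical_subject)
        assert np.allclose(a, b, rtol=1e-6)

    def test_zero_dose_gives_zero_profile(self, typical_subject):
        regimen = DosingRegimen(0.0, 12.0, 2.0, 8)
        grid = np.linspace(0.0, 96.0, 97)
        assert np.all(concentration_profile(grid, regimen, typical_subject) == 0.0)

    def test_profile_validates_grid(self, regimen_1g_q12h, typical_subject):
        with pytest.raises(ValueError):
            concentration_profile([], regimen_1g_q12h, typical_subject)
        with pytest.raises(ValueError):
            concentration_profile([5.0, 1.0], regimen_1g_q12h, typical_subject)

    def test_single_point_grid_matches_scalar(self, regimen_1g_q12h, typical_subject):
        scalar = concentration(7.0, regimen_1g_q12h, typical_subject)
        vector = concentration_profile([7.0], regimen_1g_q12h, typical_subject)
        assert vector[0] == pytest.approx(scalar, rel=1e-14)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cl=st.floats(0.5, 15.0),
    q=st.floats(0.2, 20.0),
    v1=st.floats(5.0, 60.0),
    v2=st.floats(5.0, 120.0),
    tinf=st.floats(0.5, 8.0),
)
def test_profile_nonnegative_and_matches_oracle(cl, q, v1, v2, tinf):
    """Arbitrary physiological parameter sets stay non-negative and agree
    with the ODE oracle (looser tolerance for the property sweep)."""
    subj = SubjectRealization(cl=cl, q=q, v1=v1, v2=v2, egfr=100.0)
    regimen = DosingRegimen(1000.0, 12.0, tinf, 3)
    grid = np.linspace(0.5, 36.0, 25)
    closed = concentration_profile(grid, regimen, subj)
    assert np.all(closed >= 0.0)
    oracle = ode_concentrations(grid, regimen, subj, rtol=1e-9, atol=1e-11)
    assert np.max(np.abs(closed - oracle) / np.maximum(np.abs(oracle), 1e-9)) < 1e-5
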