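import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from barofold.equilibrium import (
    TwoStateFit,
    compare_branches,
    delta_g,
    equilibrium_constant,
    fit_binding_titration,
    fit_two_state,
    fraction_unfolded,
    half_transition_pressure,
    predicted_observable,
)
from barofold.errors import InsufficientDataError, ValidationError
from barofold.synthetic import CycleTruth, simulate_profile

DIMER = CycleTruth(dG0_u=8.37, dV_u=-34.18)  # published dimer csm parameters


class TestForwardModel:
    def test_delta_g_at_atmospheric(self):
        assert delta_g(8.37, -34.18, 0.0) == pytest.approx(8370.0, rel=1e-12)

    def test_delta_g_zero_at_p_half(self):
        p_half = TwoStateFit(8.37, -34.18).p_half
        assert abs(delta_g(8.37, -34.18, p_half)) < 1.0  # J/mol

    def test_delta_g_arithmetic(self):
        assert delta_g(0.0, -100.0, 10.0) == pytest.approx(-1000.0, rel=1e-12)

    def test_equilibrium_constant_unity_at_p_half(self):
        fit = TwoStateFit(8.37, -34.18)
        assert equilibrium_constant(8.37, -34.18, fit.p_half) == pytest.approx(1.0, rel=1e-9)

    def test_equilibrium_constant_at_atmospheric(self):
        # closed form: RT = 2478.82 J/mol, dG(0.1) = 8366.58 J/mol
        assert equilibrium_constant(8.37, -34.18, 0.1) == pytest.approx(0.03421, abs=2e-5)

    def test_equilibrium_constant_monotone_when_pressure_destabilizes(self):
        p = np.linspace(0.1, 600.0, 100)
        K = equilibrium_constant(8.37, -34.18, p)
        assert np.all(np.diff(K) > 0)

    def test_no_overflow_at_extreme_pressure(self):
        assert np.isfinite(equilibrium_constant(8.37, -34.18, 1e6))

    def test_fraction_unfolded_half_at_p_half(self):
        fit = TwoStateFit(8.37, -34.18)
        assert fraction_unfolded(8.37, -34.18, fit.p_half) == pytest.approx(0.5, abs=1e-9)

    def test_fraction_unfolded_at_atmospheric(self):
        assert fraction_unfolded(8.37, -34.18, 0.1) == pytest.approx(0.0331, abs=2e-4)

    def test_fraction_unfolded_limit(self):
        # dG(p) < -20 kJ/mol ==> essentially fully unfolded
        p = (20.0 + 8.37) * 1000.0 / 34.18 + 1.0
        assert fraction_unfolded(8.37, -34.18, p) > 0.999

    @given(
        st.floats(min_value=0.5, max_value=60.0),
        st.floats(min_value=-200.0, max_value=-10.0),
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_model_at_p_half_is_midpoint_of_endpoints(self, dg, dv, yf, yu):
        p_half = -1000.0 * dg / dv
        y = predicted_observable(dg, dv, yf, yu, p_half)
        assert y == pytest.approx(0.5 * (yf + yu), rel=1e-9, abs=1e-9)

    def test_predicted_observable_monotone_in_pressure(self):
        p = np.linspace(0.1, 600.0, 200)
        y = predicted_observable(8.37, -34.18, 100.0, 50.0, p)
        assert np.all(np.diff(y) < 0)  # quenching: signal falls as f_u rises


class TestHalfTransitionPressure:
    def test_published_dimer_value(self):
        assert half_transition_pressure(TwoStateFit(8.37, -34.18)) == pytest.approx(
            244.9, abs=0.05
        )

    def test_published_decreasing_dimer_value(self):
        assert half_transition_pressure(TwoStateFit(4.52, -61.47)) == pytest.approx(
            73.53, abs=0.005
        )

    def test_zero_free_energy_gives_zero_midpoint(self):
        assert half_transition_pressure(TwoStateFit(0.0, -80.0)) == 0.0

    def test_positive_dv_undefined(self):
        with pytest.raises(ValidationError):
            half_transition_pressure(TwoStateFit(8.0, 10.0))


def _grid_search_oracle(profile, T=298.15, n=200):
    """Independent oracle: exhaustive (dG0, dV) lattice with the endpoint
    observables solved linearly at each lattice node."""
    p, y = profile.pressures, profile.values
    best = (np.inf, None)
    for dg in np.linspace(4.0, 14.0, n):
        for dv in np.linspace(-60.0, -15.0, n):
            K = equilibrium_constant(dg, dv, p, T)
            X = np.column_stack([1.0 / (1.0 + K), K / (1.0 + K)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ coef) ** 2))
            if sse < best[0]:
                best = (sse, (dg, dv, coef[0], coef[1]))
    return best


class TestFitTwoState:
    def test_noiseless_recovery_to_four_figures(self, eq_pressures):
        rng = np.random.default_rng(0)
        prof = simulate_profile(eq_pressures, DIMER, 100.0, 55.0, 0.0, rng)
        fit = fit_two_state(prof)
        assert fit.dG0_u == pytest.approx(8.37, rel=1e-4)
        assert fit.dV_u == pytest.approx(-34.18, rel=1e-4)
        assert fit.obs_f == pytest.approx(100.0, rel=1e-4)
        assert fit.obs_u == pytest.approx(55.0, rel=1e-4)

    def test_noisy_fit_matches_grid_search_oracle(self, eq_pressures):
        rng = np.random.default_rng(123)
        prof = simulate_profile(eq_pressures, DIMER, 100.0, 55.0, 0.01, rng)
        fit = fit_two_state(prof)
        sse_oracle, theta = _grid_search_oracle(prof)
        sse_fit = float(np.sum(fit.residuals**2))
        # the optimizer must do at least as well as the lattice search
        assert sse_fit <= sse_oracle * (1.0 + 1e-6)
        assert fit.dG0_u == pytest.approx(theta[0], abs=0.06)   # lattice spacing
        assert fit.dV_u == pytest.approx(theta[1], abs=0.3)
        # and recover truth within 3 asymptotic standard errors
        assert abs(fit.dG0_u - 8.37) <= 3 * fit.std_errors["dG0_u"]
        assert abs(fit.dV_u + 34.18) <= 3 * fit.std_errors["dV_u"]

    def test_p_half_identity_holds_for_fit(self, eq_pressures):
        rng = np.random.default_rng(5)
        prof = simulate_profile(eq_pressures, DIMER, 100.0, 55.0, 0.01, rng)
        fit = fit_two_state(prof)
        assert fit.p_half == pytest.approx(-1000.0 * fit.dG0_u / fit.dV_u, rel=1e-12)

    def test_affine_invariance_of_thermodynamic_parameters(self, eq_pressures):
        rng = np.random.default_rng(9)
        prof = simulate_profile(eq_pressures, DIMER, 100.0, 55.0, 0.01, rng)
        fit1 = fit_two_state(prof)
        from barofold.spectra import PressureProfile

        prof2 = PressureProfile(
            pressures=prof.pressures,
            values=3.0 * prof.values - 7.0,
            observable=prof.observable,
            branch=prof.branch,
        )
        fit2 = fit_two_state(prof2)
        assert fit2.dG0_u == pytest.approx(fit1.dG0_u, rel=1e-6)
        assert fit2.dV_u == pytest.approx(fit1.dV_u, rel=1e-6)

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(0)
        prof = simulate_profile([0.1, 150.0, 300.0, 450.0], DIMER, 100.0, 55.0, 0.0, rng)
        with pytest.raises(InsufficientDataError):
            fit_two_state(prof)

    def test_constant_observable_rejected(self):
        from barofold.spectra import PressureProfile

        prof = PressureProfile(
            pressures=np.linspace(0.1, 600, 21),
            values=np.full(21, 42.0),
            observable="intensity",
            branch="increasing",
            lambda_ref=338.0,
        )
        with pytest.raises(InsufficientDataError):
            fit_two_state(prof)

    def test_exchange_symmetry_of_parametrization(self, eq_pressures):
        # (dG0, dV, y_f, y_u) and (-dG0, -dV, y_u, y_f) describe the same
        # curve; whichever sign convention the fit lands in, p_half and the
        # predicted curve are unambiguous
        rng = np.random.default_rng(0)
        prof = simulate_profile(eq_pressures, CycleTruth(-8.37, 34.18), 55.0, 100.0, 0.0, rng)
        fit = fit_two_state(prof)
        assert -1000.0 * fit.dG0_u / fit.dV_u == pytest.approx(244.88, abs=0.1)
        assert np.allclose(fit.predict(prof.pressures), prof.values, rtol=1e-6)


class TestCompareBranches:
    def _fit(self, dg, dv, se_g=0.3, se_v=3.0):
        return TwoStateFit(dg, dv, std_errors={"dG0_u": se_g, "dV_u": se_v})

    def test_identical_fits_no_hysteresis(self):
        a = self._fit(8.37, -34.18)
        rep = compare_branches(a, a)
        assert rep.dp_half == 0.0
        assert not rep.hysteresis

    def test_published_first_cycle_hysteresis(self):
        up = self._fit(57.56, -172.60, 1.93, 5.80)
        down = self._fit(12.63, -95.71, 1.21, 9.99)
        rep = compare_branches(up, down)
        assert rep.dp_half == pytest.approx(201.0, abs=1.5)
        assert rep.hysteresis

    def test_unconverged_fit_rejected(self):
        a = self._fit(8.37, -34.18)
        b = self._fit(8.37, -34.18)
        b.converged = False
        with pytest.raises(ValidationError):
            compare_branches(a, b)


def _golden_section_oracle(L, F):
    """Independent 1-D oracle: scan Kd, F_max solved linearly at each Kd."""

    def sse(kd):
        x = L / (kd + L)
        fmax = float(np.dot(x, F) / np.dot(x, x))
        return float(np.sum((F - fmax * x) ** 2))

    res = minimize_scalar(sse, bounds=(0.01, 50.0), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestBindingTitration:
    L = np.array([0.156, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0])  # uM

    def test_half_saturation_at_kd(self):
        fit = fit_binding_titration(self.L, 100.0 * self.L / (0.8 + self.L))
        assert fit.predict(fit.Kd) == pytest.approx(fit.F_max / 2.0, rel=1e-9)

    def test_noiseless_exact_recovery(self):
        F = 100.0 * self.L / (0.8 + self.L)
        fit = fit_binding_titration(self.L, F)
        assert fit.Kd == pytest.approx(0.8, rel=1e-6)
        assert fit.F_max == pytest.approx(100.0, rel=1e-6)

    def test_noisy_recovery_matches_golden_section_oracle(self):
        rng = np.random.default_rng(21)
        F = 100.0 * self.L / (0.8 + self.L)
        F = F + 0.02 * F.max() * rng.standard_normal(F.size)
        fit = fit_binding_titration(self.L, F)
        assert fit.Kd == pytest.approx(_golden_section_oracle(self.L, F), rel=1e-4)
        assert abs(fit.Kd - 0.8) <= 3 * fit.std_errors["Kd"]

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_binding_titration([0.5, 1.0, 2.0], [30.0, 50.0, 70.0])
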