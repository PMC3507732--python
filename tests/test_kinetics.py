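import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from barofold.equilibrium import TwoStateFit
from barofold.errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from barofold.kinetics import (
    ActivationVolumes,
    KineticFit,
    RateDecomposition,
    RelaxationTrace,
    consistency_check,
    decompose_rates,
    fit_activation_volumes,
    fit_biexponential,
    fit_monoexponential,
    kobs_from_lines,
    kobs_minimum_pressure,
    select_model,
)
from barofold.units import rt


def make_trace(k=0.01, I0=1.0, A=0.5, n=300, span_factor=6.0, noise=0.0,
               seed=0, k2=None, B=0.0, p_initial=220.0, p_final=180.0):
    t = 0.005 + np.linspace(0.0, span_factor / k, n)
    y = I0 + A * np.exp(-k * t)
    if k2 is not None:
        y = y + B * np.exp(-k2 * t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + noise * abs(A) * rng.standard_normal(n)
    return RelaxationTrace(times=t, intensities=y, p_initial=p_initial,
                           p_final=p_final, dead_time=0.005)


class TestTraceValidation:
    def test_rejects_equal_pressures(self):
        t = np.linspace(0.01, 10, 50)
        with pytest.raises(ValidationError):
            RelaxationTrace(t, np.exp(-t), p_initial=100.0, p_final=100.0)

    def test_rejects_too_few_post_dead_time_samples(self):
        t = np.linspace(0.0, 0.004, 30)  # all inside the 5 ms dead time
        with pytest.raises(ValidationError):
            RelaxationTrace(t, np.exp(-t), p_initial=220.0, p_final=180.0)

    def test_direction_from_pressures(self):
        tr = make_trace(p_initial=220.0, p_final=180.0)
        assert tr.direction == "downward"
        tr = make_trace(p_initial=180.0, p_final=220.0)
        assert tr.direction == "upward"


def _log_scan_oracle(trace, k_lo=1e-4, k_hi=1.0, n=4000):
    """Independent oracle: log-spaced scan over k, (I0, A) solved linearly."""
    t, y = trace.usable()
    best = (np.inf, None)
    for k in np.geomspace(k_lo, k_hi, n):
        X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        if sse < best[0]:
            best = (sse, k)
    return best[1]


class TestMonoexponential:
    def test_noiseless_exact_recovery(self):
        fit = fit_monoexponential(make_trace(k=0.01, I0=1.0, A=0.5))
        assert fit.k_obs == pytest.approx(0.01, rel=1e-6)
        assert fit.I0 == pytest.approx(1.0, rel=1e-6)
        assert fit.A == pytest.approx(0.5, rel=1e-6)

    def test_noisy_recovery_within_3se_and_matches_scan_oracle(self):
        tr = make_trace(k=0.01, noise=0.02, seed=11)
        fit = fit_monoexponential(tr)
        assert abs(fit.k_obs - 0.01) <= 3 * fit.std_errors["k_obs"]
        assert fit.k_obs == pytest.approx(_log_scan_oracle(tr), rel=2e-3)

    def test_zero_amplitude_degenerate(self):
        t = 0.005 + np.linspace(0, 600, 200)
        tr = RelaxationTrace(t, np.full_like(t, 2.0), p_initial=220.0, p_final=180.0)
        with pytest.raises(DegenerateFitError):
            fit_monoexponential(tr)

    def test_short_trace_flagged(self):
        fit = fit_monoexponential(make_trace(k=0.01, span_factor=1.0))
        assert any("2/k_obs" in w for w in fit.warnings)


def _grid2d_oracle(trace):
    """Independent oracle: coarse (k1, k2) grid with linear amplitudes."""
    t, y = trace.usable()
    best = (np.inf, None)
    for k1 in np.geomspace(0.02, 0.5, 60):
        for k2 in np.geomspace(4e-4, 0.01, 60):
            X = np.column_stack([np.ones_like(t), np.exp(-k1 * t), np.exp(-k2 * t)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ coef) ** 2))
            if sse < best[0]:
                best = (sse, (k1, k2))
    return best[1]


class TestBiexponential:
    def test_noiseless_recovery(self):
        tr = make_trace(k=0.1, A=0.4, k2=0.002, B=0.3, span_factor=300.0, n=2000)
        fit = fit_biexponential(tr)
        assert fit.k_obs == pytest.approx(0.1, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.002, rel=1e-4)
        assert fit.k_obs > fit.k_slow

    def test_noisy_fast_phase_within_3se_and_matches_grid_oracle(self):
        tr = make_trace(k=0.1, A=0.4, k2=0.002, B=0.3, span_factor=300.0,
                        n=2000, noise=0.02, seed=3)
        fit = fit_biexponential(tr)
        assert abs(fit.k_obs - 0.1) <= 3 * fit.std_errors["k_obs"]
        k1_oracle, _ = _grid2d_oracle(tr)
        # grid spacing ~5.6%; the optimizer should land in the same cell
        assert fit.k_obs == pytest.approx(k1_oracle, rel=0.06)

    def test_ill_separated_phases_flagged(self):
        tr = make_trace(k=0.01, A=0.4, k2=0.005, B=0.4, span_factor=8.0, n=800)
        fit = fit_biexponential(tr)
        assert any("ill-separated" in w for w in fit.warnings)


class TestModelSelection:
    def test_mono_data_selects_mono(self):
        tr = make_trace(k=0.01, noise=0.01, seed=2)
        assert select_model(fit_monoexponential(tr), fit_biexponential(tr)) == "mono"

    def test_biphasic_data_selects_bi(self):
        tr = make_trace(k=0.1, A=0.4, k2=0.002, B=0.3, span_factor=300.0,
                        n=2000, noise=0.005, seed=4)
        assert select_model(fit_monoexponential(tr), fit_biexponential(tr)) == "bi"

    def test_tie_resolves_to_mono(self):
        mono = KineticFit(model="mono", k_obs=0.01, A=1.0, I0=0.0, aicc=-100.0, n_points=50)
        bi = KineticFit(model="bi", k_obs=0.02, k_slow=0.001, A=0.5, B=0.5,
                        I0=0.0, aicc=-101.5, n_points=50)
        assert select_model(mono, bi) == "mono"


class TestDecomposeRates:
    EQ = TwoStateFit(8.37, -34.18)

    def test_symmetric_split_at_p_half(self):
        dec = decompose_rates(0.01, self.EQ.p_half, self.EQ)
        assert dec.k_f == pytest.approx(0.005, rel=1e-9)
        assert dec.k_u == pytest.approx(0.005, rel=1e-9)

    def test_algebra_for_known_K(self):
        # K = 3 at a pressure solved from the truth parameters
        from barofold.units import rt as _rt
        p = (8.37 * 1000.0 - (-math.log(3.0)) * _rt(298.15)) / 34.18
        dec = decompose_rates(0.01, p, self.EQ)
        assert dec.K_p == pytest.approx(3.0, rel=1e-9)
        assert dec.k_u == pytest.approx(0.0075, rel=1e-9)
        assert dec.k_f == pytest.approx(0.0025, rel=1e-9)

    def test_atmospheric_split_matches_closed_form(self):
        dec = decompose_rates(0.02, 0.1, self.EQ)
        K = self.EQ.equilibrium_constant(0.1)
        assert dec.k_u == pytest.approx(0.02 * K / (1 + K), rel=1e-12)
        assert dec.k_f == pytest.approx(0.02 / (1 + K), rel=1e-12)

    @given(
        st.floats(min_value=1e-4, max_value=10.0),
        st.floats(min_value=0.1, max_value=600.0),
    )
    def test_machine_precision_invariants(self, k_obs, p):
        dec = decompose_rates(k_obs, p, self.EQ)
        assert dec.k_f + dec.k_u == pytest.approx(k_obs, rel=1e-14)
        assert dec.k_u / dec.k_f == pytest.approx(dec.K_p, rel=1e-12)


def _decomp(p, k_f, k_u):
    return RateDecomposition(p=p, k_f=k_f, k_u=k_u, K_p=k_u / k_f)


class TestActivationVolumes:
    def test_closed_form_slope_recovery(self):
        # ln k_f drops by 95*100/RT per 100 MPa for dV_act_f = +95 ml/mol
        RT = rt(298.15)
        ps = [100.0, 150.0, 200.0]
        decs = [
            _decomp(p, math.exp(1.0 - 95.0 * p / RT), math.exp(-6.0 + 5.5 * p / RT))
            for p in ps
        ]
        act = fit_activation_volumes(decs)
        assert act.dV_act_f == pytest.approx(95.0, rel=1e-9)
        assert act.dV_act_u == pytest.approx(-5.5, rel=1e-9)

    def test_flat_line_gives_zero_activation_volume(self):
        decs = [_decomp(p, 0.01, 0.02) for p in (60.0, 180.0, 300.0)]
        act = fit_activation_volumes(decs)
        assert act.dV_act_f == pytest.approx(0.0, abs=1e-9)
        assert act.dV_act_u == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_pressures_rejected(self):
        decs = [_decomp(p, 0.01, 0.02) for p in (60.0, 300.0)]
        with pytest.raises(InsufficientDataError):
            fit_activation_volumes(decs)

    def test_crossing_pressure_solves_line_equality(self):
        act = ActivationVolumes(dV_act_f=95.0, dV_act_u=-5.5,
                                ln_kf0=1.6001, ln_ku0=-5.6977)
        pc = act.crossing_pressure
        assert act.ln_kf(pc) == pytest.approx(act.ln_ku(pc), abs=1e-9)


class TestKobsReconstruction:
    ACT = ActivationVolumes(dV_act_f=95.0, dV_act_u=-5.5,
                            ln_kf0=1.60013, ln_ku0=-5.69770)

    def test_single_interior_minimum(self):
        p = np.linspace(0.1, 600.0, 6000)
        k = kobs_from_lines(self.ACT, p)
        interior_minima = np.nonzero((k[1:-1] < k[:-2]) & (k[1:-1] < k[2:]))[0]
        assert interior_minima.size == 1

    def test_analytic_minimum_matches_numeric(self):
        p = np.linspace(0.1, 600.0, 60001)
        k = kobs_from_lines(self.ACT, p)
        p_min_numeric = p[int(np.argmin(k))]
        assert kobs_minimum_pressure(self.ACT) == pytest.approx(p_min_numeric, abs=0.02)

    def test_rate_law_monotonicity(self):
        p = np.linspace(0.1, 600.0, 100)
        assert np.all(np.diff(self.ACT.ln_kf(p)) < 0)  # dV_act_f > 0 slows folding
        assert np.all(np.diff(self.ACT.ln_ku(p)) > 0)  # dV_act_u < 0 speeds unfolding

    def test_same_sign_slopes_have_no_minimum(self):
        act = ActivationVolumes(dV_act_f=95.0, dV_act_u=50.0, ln_kf0=1.0, ln_ku0=0.0)
        with pytest.raises(ValidationError):
            kobs_minimum_pressure(act)


class TestConsistencyCheck:
    def test_published_values_imply_minus_100p5(self):
        act = ActivationVolumes(dV_act_f=95.0, dV_act_u=-5.5, ln_kf0=1.6, ln_ku0=-5.7,
                                std_errors={"dV_act_f": 8.0, "dV_act_u": 0.7})
        eq = TwoStateFit(18.09, -100.5, std_errors={"dV_u": 5.0})
        rep = consistency_check(act, eq)
        assert rep.implied_dV_u == pytest.approx(-100.5, rel=1e-12)
        assert rep.consistent

    def test_mismatched_equilibrium_flagged(self):
        act = ActivationVolumes(dV_act_f=95.0, dV_act_u=-5.5, ln_kf0=1.6, ln_ku0=-5.7,
                                std_errors={"dV_act_f": 1.0, "dV_act_u": 0.1})
        eq = TwoStateFit(8.37, -34.18, std_errors={"dV_u": 1.24})
        rep = consistency_check(act, eq)
        assert not rep.consistent
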