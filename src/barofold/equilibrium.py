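"""Two-state pressure-unfolding thermodynamics.

Model: folded (N) and unfolded (U) states exchange with a pressure-linear
free energy of unfolding

    dG(p) = dG0_u + p * dV_u        [dG0_u in kJ/mol, dV_u in ml/mol, p in MPa]

so that K(p) = exp(-dG(p)/RT) and the observed signal is the population-
weighted Boltzmann mixture

    y(p) = (y_f + y_u * K(p)) / (1 + K(p)).

A negative dV_u means pressure favors unfolding; the transition midpoint is
p_half = -1000 * dG0_u / dV_u (MPa). The published presentation of this model
leaves the equation body to a figure; the canonical two-state form above is
implemented, consistent with the surrounding parameter definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from barofold.errors import (
    FitFailureError,
    InsufficientDataError,
    ValidationError,
)
from barofold.spectra import PressureProfile
from barofold.units import DEFAULT_T, KJ_TO_J, rt

_EXP_CLAMP = 700.0  # |exponent| cap; exp(700) is near the float64 ceiling


def delta_g(dG0_u: float, dV_u: float, p) -> float:
    """Free energy of unfolding at pressure p, in J/mol.

    dG0_u in kJ/mol, dV_u in ml/mol, p in MPa; 1 MPa*ml/mol = 1 J/mol.
    """
    return KJ_TO_J * dG0_u + np.asarray(p, dtype=float) * dV_u


def equilibrium_constant(dG0_u: float, dV_u: float, p, T: float = DEFAULT_T):
    """K(p) = exp(-dG(p)/RT), with the exponent clamped at +/-700."""
    x = -delta_g(dG0_u, dV_u, p) / rt(T)
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def fraction_unfolded(dG0_u: float, dV_u: float, p, T: float = DEFAULT_T):
    """Unfolded population f_u = K/(1+K), in [0, 1]."""
    K = equilibrium_constant(dG0_u, dV_u, p, T)
    return K / (1.0 + K)


def predicted_observable(
    dG0_u: float, dV_u: float, obs_f: float, obs_u: float, p, T: float = DEFAULT_T
):
    """Two-state forward model y(p) = (y_f + y_u K)/(1 + K)."""
    K = equilibrium_constant(dG0_u, dV_u, p, T)
    return (obs_f + obs_u * K) / (1.0 + K)


def _p_half(dG0_u: float, dV_u: float) -> float:
    if dV_u >= 0:
        raise ValidationError(
            f"transition midpoint undefined for dV_u = {dV_u} >= 0 ml/mol"
        )
    return -KJ_TO_J * dG0_u / dV_u


@dataclass
class TwoStateFit:
    """Fitted (or assumed) two-state parameters for one pressure profile."""

    dG0_u: float                 # kJ/mol at 0.1 MPa
    dV_u: float                  # ml/mol
    obs_f: float = 0.0           # folded-state observable
    obs_u: float = 1.0           # unfolded-state observable
    T: float = DEFAULT_T         # K
    std_errors: dict = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None
    converged: bool = True
    warnings: list = field(default_factory=list)
    profile: Optional[PressureProfile] = None

    @property
    def p_half(self) -> float:
        """Midpoint pressure -1000*dG0_u/dV_u [MPa]; requires dV_u < 0."""
        return _p_half(self.dG0_u, self.dV_u)

    @property
    def p_half_se(self) -> float:
        """Gaussian-propagated SE of p_half from the dG0/dV SEs."""
        se_g = self.std_errors.get("dG0_u", 0.0)
        se_v = self.std_errors.get("dV_u", 0.0)
        g, v = self.dG0_u, self.dV_u
        return math.hypot(KJ_TO_J * se_g / v, KJ_TO_J * g * se_v / v**2)

    def delta_g(self, p):
        return delta_g(self.dG0_u, self.dV_u, p)

    def equilibrium_constant(self, p, T: Optional[float] = None):
        return equilibrium_constant(self.dG0_u, self.dV_u, p, T or self.T)

    def fraction_unfolded(self, p, T: Optional[float] = None):
        return fraction_unfolded(self.dG0_u, self.dV_u, p, T or self.T)

    def predict(self, p):
        return predicted_observable(self.dG0_u, self.dV_u, self.obs_f, self.obs_u, p, self.T)

    def to_dict(self) -> dict:
        d = {
            "dG0_u_kJ_mol": self.dG0_u,
            "dV_u_ml_mol": self.dV_u,
            "obs_f": self.obs_f,
            "obs_u": self.obs_u,
            "T_K": self.T,
            "std_errors": dict(self.std_errors),
            "converged": self.converged,
            "warnings": list(self.warnings),
        }
        try:
            d["p_half_MPa"] = self.p_half
            d["p_half_se_MPa"] = self.p_half_se
        except ValidationError:
            d["p_half_MPa"] = None
        if self.residuals is not None:
            d["residual_norm"] = float(np.linalg.norm(self.residuals))
        return d


def half_transition_pressure(fit: TwoStateFit) -> float:
    """p_half = -1000*dG0_u/dV_u [MPa] for an unfolding transition (dV_u < 0)."""
    if fit.dG0_u < 0:
        raise ValidationError("p_half is defined for stable folds (dG0_u >= 0)")
    return _p_half(fit.dG0_u, fit.dV_u)


def _initial_guess(p: np.ndarray, y: np.ndarray, T: float):
    """Heuristic start: endpoints from the outer 10% of points, dV at -50."""
    k = max(1, int(round(0.1 * len(p))))
    obs_f = float(np.mean(y[:k]))
    obs_u = float(np.mean(y[-k:]))
    mid = 0.5 * (obs_f + obs_u)
    # pressure where the observable first crosses its midpoint
    crossed = np.nonzero(np.sign(y - mid) != np.sign(y[0] - mid))[0]
    p_half0 = float(p[crossed[0]]) if crossed.size else float(np.median(p))
    p_half0 = max(p_half0, 1.0)
    dV0 = -50.0
    dG0 = -p_half0 * dV0 / KJ_TO_J
    return dG0, dV0, obs_f, obs_u


def fit_two_state(
    profile: PressureProfile,
    T: float = DEFAULT_T,
    linear_baselines: bool = False,
) -> TwoStateFit:
    """Unweighted least-squares fit of the two-state model to a profile.

    Fits (dG0_u, dV_u, obs_f, obs_u); with ``linear_baselines`` the endpoint
    observables acquire pressure-linear slopes (a robustness option, off by
    default since the published analysis uses constant endpoints). Standard
    errors are asymptotic, from the Jacobian at the optimum.
    """
    profile.require_fittable()
    p = profile.pressures
    y = profile.values
    if np.ptp(y) <= 0:
        raise InsufficientDataError("observable does not vary; nothing to fit")

    dG0, dV0, f0, u0 = _initial_guess(p, y, T)

    if linear_baselines:
        def model(pp, g, v, yf, yu, mf, mu):
            return predicted_observable(g, v, yf + mf * pp, yu + mu * pp, pp, T)
        p0 = [dG0, dV0, f0, u0, 0.0, 0.0]
        names = ["dG0_u", "dV_u", "obs_f", "obs_u", "slope_f", "slope_u"]
    else:
        def model(pp, g, v, yf, yu):
            return predicted_observable(g, v, yf, yu, pp, T)
        p0 = [dG0, dV0, f0, u0]
        names = ["dG0_u", "dV_u", "obs_f", "obs_u"]

    try:
        popt, pcov = curve_fit(model, p, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"two-state fit failed to converge: {exc}",
            diagnostics={"p0": p0, "n_points": len(p)},
        ) from exc

    perr = np.sqrt(np.diag(pcov))
    fitted = dict(zip(names, popt))
    ses = {n: float(s) for n, s in zip(names, perr)}
    resid = y - model(p, *popt)

    warn: list[str] = []
    if fitted["dV_u"] >= 0:
        warn.append("fitted dV_u >= 0 on an unfolding profile")
    if not np.all(np.isfinite(perr)):
        warn.append("singular covariance; standard errors unreliable")

    return TwoStateFit(
        dG0_u=float(fitted["dG0_u"]),
        dV_u=float(fitted["dV_u"]),
        obs_f=float(fitted["obs_f"]),
        obs_u=float(fitted["obs_u"]),
        T=T,
        std_errors=ses,
        residuals=resid,
        converged=True,
        warnings=warn,
        profile=profile,
    )


@dataclass
class HysteresisReport:
    """Comparison of increasing- vs decreasing-pressure fits."""

    dp_half: float          # p_half(up) - p_half(down), MPa
    dp_half_se: float
    d_dV: float             # dV(up) - dV(down), ml/mol
    d_dV_se: float
    d_dG0: float            # kJ/mol
    d_dG0_se: float
    hysteresis: bool        # |dp_half| > 2 * dp_half_se

    def to_dict(self) -> dict:
        return {
            "dp_half_MPa": self.dp_half,
            "dp_half_se_MPa": self.dp_half_se,
            "d_dV_ml_mol": self.d_dV,
            "d_dV_se_ml_mol": self.d_dV_se,
            "d_dG0_kJ_mol": self.d_dG0,
            "d_dG0_se_kJ_mol": self.d_dG0_se,
            "hysteresis": self.hysteresis,
        }


def compare_branches(fit_up: TwoStateFit, fit_down: TwoStateFit) -> HysteresisReport:
    """Hysteresis report between the two branches of one pressurization cycle.

    Flags hysteresis when the midpoint shift exceeds twice its propagated
    standard error.
    """
    if not (fit_up.converged and fit_down.converged):
        raise ValidationError("both fits must have converged")
    dp = fit_up.p_half - fit_down.p_half
    dp_se = math.hypot(fit_up.p_half_se, fit_down.p_half_se)
    ddv = fit_up.dV_u - fit_down.dV_u
    ddv_se = math.hypot(
        fit_up.std_errors.get("dV_u", 0.0), fit_down.std_errors.get("dV_u", 0.0)
    )
    ddg = fit_up.dG0_u - fit_down.dG0_u
    ddg_se = math.hypot(
        fit_up.std_errors.get("dG0_u", 0.0), fit_down.std_errors.get("dG0_u", 0.0)
    )
    return HysteresisReport(
        dp_half=dp,
        dp_half_se=dp_se,
        d_dV=ddv,
        d_dV_se=ddv_se,
        d_dG0=ddg,
        d_dG0_se=ddg_se,
        hysteresis=bool(abs(dp) > 2.0 * dp_se),
    )


@dataclass
class BindingFit:
    """Hyperbolic (1:1) ligand-binding fit: F = F_max * L / (Kd + L)."""

    Kd: float        # uM
    F_max: float
    std_errors: dict = field(default_factory=dict)

    def predict(self, L):
        return self.F_max * np.asarray(L, dtype=float) / (self.Kd + np.asarray(L, dtype=float))


def fit_binding_titration(ligand_conc, F) -> BindingFit:
    """Fit a hyperbolic titration curve; concentrations in uM.

    At L = Kd the model gives F_max / 2.
    """
    L = np.asarray(ligand_conc, dtype=float)
    y = np.asarray(F, dtype=float)
    if L.size < 4:
        raise InsufficientDataError("need >= 4 concentrations spanning Kd")
    if np.any(L <= 0):
        raise ValidationError("ligand concentrations must be positive")

    def model(l, kd, fmax):
        return fmax * l / (kd + l)

    p0 = [float(np.median(L)), float(np.max(y))]
    try:
        popt, pcov = curve_fit(
            model, L, y, p0=p0, bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"binding fit failed: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return BindingFit(
        Kd=float(popt[0]),
        F_max=float(popt[1]),
        std_errors={"Kd": float(perr[0]), "F_max": float(perr[1])},
    )
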