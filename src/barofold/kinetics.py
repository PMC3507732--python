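"""Pressure-jump relaxation kinetics.

After a rapid pressure jump a two-state system relaxes mono-exponentially
with observed rate k_obs(p) = k_f(p) + k_u(p). Combining k_obs with the
equilibrium constant K(p) = k_u/k_f from the thermodynamic fit splits the
observed rate into its folding and unfolding components:

    k_u = k_obs * K / (1 + K),    k_f = k_obs / (1 + K).

The pressure dependence of each rate constant defines an activation volume
through ln k(p) = ln k(0) - p * dV_act / RT; a positive dV_act_f means the
transition state is larger than the unfolded state so pressure slows folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from barofold.equilibrium import TwoStateFit
from barofold.errors import (
    DegenerateFitError,
    FitFailureError,
    InsufficientDataError,
    ValidationError,
)
from barofold.units import DEFAULT_T, rt

DEFAULT_DEAD_TIME = 0.005  # s; instrument dead time of the pressure-jump valve


@dataclass(frozen=True)
class RelaxationTrace:
    """Intensity time-course following one pressure jump."""

    times: np.ndarray          # s, strictly increasing, non-negative
    intensities: np.ndarray
    p_initial: float           # MPa
    p_final: float             # MPa
    cycle: int = 1
    dead_time: float = DEFAULT_DEAD_TIME  # s; samples before this are excluded

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.size != y.size:
            raise ValidationError("times and intensities must have equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        if self.p_initial == self.p_final:
            raise ValidationError("p_initial must differ from p_final")
        if self.dead_time < 0:
            raise ValidationError("dead_time must be non-negative")
        if np.count_nonzero(t >= self.dead_time) < 20:
            raise ValidationError(
                "need >= 20 samples after dead-time truncation"
            )

    @property
    def direction(self) -> Literal["upward", "downward"]:
        return "upward" if self.p_final > self.p_initial else "downward"

    def usable(self):
        """(t, y) with the dead-time window removed."""
        m = self.times >= self.dead_time
        return self.times[m], self.intensities[m]


@dataclass
class KineticFit:
    """Mono- or bi-exponential fit of one relaxation trace.

    For the bi-exponential model the fast phase is exported as k_obs, per the
    convention that the fast phase carries the folding/unfolding relaxation.
    """

    model: Literal["mono", "bi"]
    k_obs: float               # s^-1 (mono rate, or fast phase of bi)
    A: float
    I0: float
    k_slow: Optional[float] = None
    B: Optional[float] = None
    std_errors: dict = field(default_factory=dict)
    aicc: float = math.nan
    n_points: int = 0
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.k_obs <= 0:
            raise ValidationError("k_obs must be positive")
        if self.model == "bi" and (self.k_slow is None or self.k_obs <= self.k_slow):
            raise ValidationError("bi model requires k_obs > k_slow > 0")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k_obs_per_s": self.k_obs,
            "k_slow_per_s": self.k_slow,
            "A": self.A,
            "B": self.B,
            "I0": self.I0,
            "std_errors": dict(self.std_errors),
            "aicc": self.aicc,
            "warnings": list(self.warnings),
        }


def _aicc(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian residuals."""
    if n <= k + 1:
        return math.inf
    return n * math.log(max(sse, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _check_informative(y: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.ptp(y) < 1e-12 * scale:
        raise DegenerateFitError(
            "trace amplitude is zero; the relaxation rate is unidentifiable"
        )
    return scale


def fit_monoexponential(trace: RelaxationTrace) -> KineticFit:
    """Fit I(t) = I0 + A*exp(-k_obs*t) on samples with t >= dead_time."""
    t, y = trace.usable()
    scale = _check_informative(y)

    I0_0 = float(y[-1])
    A0 = float(y[0] - y[-1])
    span = float(t[-1] - t[0])
    k0 = 3.0 / span if span > 0 else 1.0

    def model(tt, i0, a, k):
        return i0 + a * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[I0_0, A0, k0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"mono-exponential fit failed: {exc}") from exc

    i0, a, k = (float(v) for v in popt)
    if abs(a) < 1e-9 * scale:
        raise DegenerateFitError("fitted amplitude is zero; rate unidentifiable")
    if k <= 2e-12:
        raise FitFailureError("rate constant pinned at the lower bound")
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(t, *popt)
    warns = []
    if span * k < 2.0:
        warns.append("trace spans < 2/k_obs; rate poorly constrained")
    return KineticFit(
        model="mono", k_obs=k, A=a, I0=i0,
        std_errors={"I0": float(perr[0]), "A": float(perr[1]), "k_obs": float(perr[2])},
        aicc=_aicc(float(np.sum(resid**2)), len(t), 3),
        n_points=len(t),
        warnings=warns,
    )


def fit_biexponential(trace: RelaxationTrace) -> KineticFit:
    """Fit I(t) = I0 + A*exp(-k1*t) + B*exp(-k2*t), ordered k1 > k2.

    The fast phase is exported as k_obs. Phases separated by less than a
    factor of 3 are flagged as ill-separated.
    """
    t, y = trace.usable()
    _check_informative(y)

    mono = fit_monoexponential(trace)
    k1_0, k2_0 = mono.k_obs * 5.0, mono.k_obs / 5.0

    def model(tt, i0, a, b, k1, k2):
        return i0 + a * np.exp(-k1 * tt) + b * np.exp(-k2 * tt)

    p0 = [mono.I0, mono.A / 2.0, mono.A / 2.0, k1_0, k2_0]
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf] * 3 + [1e-12, 1e-12], [np.inf] * 5),
            maxfev=40000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"bi-exponential fit failed: {exc}") from exc

    i0, a, b, k1, k2 = (float(v) for v in popt)
    perr = [float(v) for v in np.sqrt(np.diag(pcov))]
    if k1 < k2:  # enforce fast-phase-first ordering
        a, b = b, a
        k1, k2 = k2, k1
        perr = [perr[0], perr[2], perr[1], perr[4], perr[3]]
    if math.isclose(k1, k2, rel_tol=1e-9):
        k2 = k1 * (1 - 1e-9)  # keep the k_obs > k_slow invariant on degenerate fits
    resid = y - model(t, *popt)
    warns = []
    if k1 / k2 < 3.0:
        warns.append("phases ill-separated (k1/k2 < 3)")
    return KineticFit(
        model="bi", k_obs=k1, k_slow=k2, A=a, B=b, I0=i0,
        std_errors={
            "I0": perr[0], "A": perr[1], "B": perr[2],
            "k_obs": perr[3], "k_slow": perr[4],
        },
        aicc=_aicc(float(np.sum(resid**2)), len(t), 5),
        n_points=len(t),
        warnings=warns,
    )


def select_model(mono: KineticFit, bi: KineticFit) -> Literal["mono", "bi"]:
    """Pick mono vs bi by corrected-AIC; ties (|dAICc| < 2) go to mono."""
    if mono.model != "mono" or bi.model != "bi":
        raise ValidationError("pass the mono fit first and the bi fit second")
    if mono.n_points != bi.n_points:
        raise ValidationError("fits must come from the same trace")
    return "bi" if (mono.aicc - bi.aicc) >= 2.0 else "mono"


@dataclass(frozen=True)
class RateDecomposition:
    """k_obs split into folding/unfolding components at one pressure."""

    p: float        # MPa
    k_f: float      # s^-1
    k_u: float      # s^-1
    K_p: float      # equilibrium constant used for the split
    eq_source: Optional[TwoStateFit] = None

    def __post_init__(self):
        if self.k_f <= 0 or self.k_u <= 0:
            raise ValidationError("rate constants must be positive")


def decompose_rates(
    k_obs: float, p: float, eq: TwoStateFit, T: float = DEFAULT_T
) -> RateDecomposition:
    """Split k_obs into (k_f, k_u) using K(p) from an equilibrium fit.

    By construction k_f + k_u = k_obs and k_u/k_f = K(p) to machine precision.
    """
    if k_obs <= 0:
        raise ValidationError("k_obs must be positive")
    if not eq.converged:
        raise ValidationError("equilibrium fit did not converge")
    K = float(eq.equilibrium_constant(p, T))
    k_u = k_obs * K / (1.0 + K)
    k_f = k_obs / (1.0 + K)
    return RateDecomposition(p=float(p), k_f=k_f, k_u=k_u, K_p=K, eq_source=eq)


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Slope/intercept with classical OLS standard errors."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 0:
        raise ValidationError("pressures are all identical")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(np.sum(resid**2) / dof) if dof > 0 else math.nan
    se_slope = math.sqrt(s2 / sxx) if dof > 0 else math.nan
    se_intercept = math.sqrt(s2 * (1.0 / n + xm**2 / sxx)) if dof > 0 else math.nan
    return slope, intercept, se_slope, se_intercept


@dataclass
class ActivationVolumes:
    """Log-linear rate laws ln k = a - p*dV_act/RT fitted for both rates."""

    dV_act_f: float            # ml/mol
    dV_act_u: float            # ml/mol
    ln_kf0: float              # intercept ln k_f at p = 0
    ln_ku0: float
    T: float = DEFAULT_T
    std_errors: dict = field(default_factory=dict)

    @property
    def slope_f(self) -> float:
        """d ln k_f / dp [1/MPa]."""
        return -self.dV_act_f / rt(self.T)

    @property
    def slope_u(self) -> float:
        return -self.dV_act_u / rt(self.T)

    @property
    def crossing_pressure(self) -> float:
        """Pressure where the two fitted lines cross (k_f = k_u) [MPa]."""
        ds = self.slope_f - self.slope_u
        if ds == 0:
            raise ValidationError("parallel rate lines never cross")
        return (self.ln_ku0 - self.ln_kf0) / ds

    def ln_kf(self, p):
        return self.ln_kf0 + self.slope_f * np.asarray(p, dtype=float)

    def ln_ku(self, p):
        return self.ln_ku0 + self.slope_u * np.asarray(p, dtype=float)

    def to_dict(self) -> dict:
        return {
            "dV_act_f_ml_mol": self.dV_act_f,
            "dV_act_u_ml_mol": self.dV_act_u,
            "ln_kf0": self.ln_kf0,
            "ln_ku0": self.ln_ku0,
            "T_K": self.T,
            "std_errors": dict(self.std_errors),
            "crossing_pressure_MPa": self.crossing_pressure,
        }


def fit_activation_volumes(
    decomps: Sequence[RateDecomposition],
    T: float = DEFAULT_T,
    weights: Optional[np.ndarray] = None,
) -> ActivationVolumes:
    """OLS lines through (p, ln k_f) and (p, ln k_u); dV_act = -slope * RT.

    Requires >= 3 distinct pressures spanning >= 100 MPa (warns, does not
    fail, on a narrow span). Unweighted by default; ``weights`` applies
    relative weights to both ln-rate fits.
    """
    if len(decomps) < 3:
        raise InsufficientDataError(
            f"activation-volume fit needs >= 3 pressures, got {len(decomps)}"
        )
    p = np.array([d.p for d in decomps], dtype=float)
    if np.unique(p).size < 3:
        raise InsufficientDataError("need >= 3 distinct pressures")
    lnkf = np.log([d.k_f for d in decomps])
    lnku = np.log([d.k_u for d in decomps])

    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        # weighted OLS by rescaling; SEs then come from the weighted residuals
        def wfit(y):
            X = np.column_stack([np.ones_like(p), p]) * w[:, None]
            yy = y * w
            coef, res, *_ = np.linalg.lstsq(X, yy, rcond=None)
            dof = len(p) - 2
            s2 = float(res[0] / dof) if (dof > 0 and res.size) else math.nan
            cov = s2 * np.linalg.inv(X.T @ X)
            return coef[1], coef[0], math.sqrt(cov[1, 1]), math.sqrt(cov[0, 0])
        sf, af, se_sf, se_af = wfit(lnkf)
        su, au, se_su, se_au = wfit(lnku)
    else:
        sf, af, se_sf, se_af = _ols_line(p, lnkf)
        su, au, se_su, se_au = _ols_line(p, lnku)

    RT = rt(T)
    return ActivationVolumes(
        dV_act_f=-sf * RT,
        dV_act_u=-su * RT,
        ln_kf0=af,
        ln_ku0=au,
        T=T,
        std_errors={
            "dV_act_f": se_sf * RT,
            "dV_act_u": se_su * RT,
            "ln_kf0": se_af,
            "ln_ku0": se_au,
        },
    )


def kobs_from_lines(act: ActivationVolumes, p):
    """Reconstructed k_obs(p) = exp(ln k_f(p)) + exp(ln k_u(p))."""
    return np.exp(act.ln_kf(p)) + np.exp(act.ln_ku(p))


def kobs_minimum_pressure(act: ActivationVolumes) -> float:
    """Pressure of the interior minimum of the reconstructed k_obs(p).

    Exists iff the two log-linear laws have slopes of opposite sign (pressure
    slows one reaction and speeds the other); solving d k_obs/dp = 0 gives

        p_min = p_cross + ln(|s_f| / |s_u|) / (|s_f| + |s_u|)

    with s the ln-rate slopes. This is the "dip" between the folding- and
    unfolding-dominated regimes.
    """
    sf, su = act.slope_f, act.slope_u
    if sf * su >= 0:
        raise ValidationError(
            "k_obs(p) has no interior minimum unless the rate-law slopes have opposite signs"
        )
    # solve s_f*k_f(p) + s_u*k_u(p) = 0
    return float(
        (math.log(-sf / su) + act.ln_kf0 - act.ln_ku0) / (act.slope_u - sf)
    )


@dataclass
class ConsistencyReport:
    """Thermodynamic-kinetic identity check: dV_act_u - dV_act_f vs dV_u."""

    implied_dV_u: float     # ml/mol, from the activation volumes
    eq_dV_u: float          # ml/mol, from the equilibrium fit
    difference: float
    difference_se: float
    consistent: bool        # |difference| <= 2 sigma

    def to_dict(self) -> dict:
        return {
            "implied_dV_u_ml_mol": self.implied_dV_u,
            "eq_dV_u_ml_mol": self.eq_dV_u,
            "difference_ml_mol": self.difference,
            "difference_se_ml_mol": self.difference_se,
            "consistent": self.consistent,
        }


def consistency_check(act: ActivationVolumes, eq: TwoStateFit) -> ConsistencyReport:
    """Check dV_act_u - dV_act_f == dV_u (follows from K = k_u/k_f).

    Flags a discrepancy beyond two propagated standard errors.
    """
    implied = act.dV_act_u - act.dV_act_f
    diff = implied - eq.dV_u
    se = math.sqrt(
        act.std_errors.get("dV_act_u", 0.0) ** 2
        + act.std_errors.get("dV_act_f", 0.0) ** 2
        + eq.std_errors.get("dV_u", 0.0) ** 2
    )
    consistent = bool(abs(diff) <= 2.0 * se) if se > 0 else bool(abs(diff) < 1e-6)
    return ConsistencyReport(
        implied_dV_u=implied,
        eq_dV_u=eq.dV_u,
        difference=diff,
        difference_se=se,
        consistent=consistent,
    )
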