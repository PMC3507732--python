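"""Synthetic data with the statistical structure the analysis assumes.

Three generators mirror the three experimental input kinds:

* emission spectra as two-state Boltzmann mixtures of a folded band
  (csm 344 nm) and an unfolded band (csm 351 nm), with a quantum-yield ratio
  q < 1 emulating the observed pressure quenching;
* pressure-jump relaxation traces, mono-exponential by default, generated
  from log-linear rate laws ln k = ln k(0) - p*dV_act/RT and relaxing toward
  the equilibrium intensity at the final pressure;
* SEC chromatograms as Gaussian elution peaks placed by inverting a
  calibration line, together with a standards table for calibration fitting.

The default two-cycle scenario reproduces the hysteretic experiment: the
first pressurization of the substrate-bound dimer follows the
"dimer + ligand" truth, while the first decompression and the whole second
cycle follow the post-dissociation (monomer-like) truth, emulating the
irreversible loss of substrate and dimer dissociation above ~350 MPa.

Every stochastic draw derives from an explicit integer seed; identical
(config, seed) reproduce byte-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from barofold import datasets
from barofold.equilibrium import TwoStateFit, fraction_unfolded, predicted_observable
from barofold.errors import ValidationError
from barofold.kinetics import RelaxationTrace, DEFAULT_DEAD_TIME
from barofold.sec import Chromatogram, Standard
from barofold.spectra import (
    Branch,
    PressureProfile,
    Spectrum,
    compute_csm,
    wavelength_to_wavenumber,
)
from barofold.units import DEFAULT_T, KJ_TO_J, rt


@dataclass(frozen=True)
class CycleTruth:
    """Equilibrium ground truth for one pressurization regime."""

    dG0_u: float  # kJ/mol
    dV_u: float   # ml/mol

    @property
    def p_half(self) -> float:
        return -KJ_TO_J * self.dG0_u / self.dV_u

    def as_fit(self, obs_f: float = 1.0, obs_u: float = 0.0, T: float = DEFAULT_T) -> TwoStateFit:
        return TwoStateFit(dG0_u=self.dG0_u, dV_u=self.dV_u, obs_f=obs_f, obs_u=obs_u, T=T)


@dataclass(frozen=True)
class KineticTruth:
    """Log-linear rate-law ground truth.

    Parameterized by the activation volumes plus the pressure at which the
    two lines cross and the common rate there (the intercepts follow). The
    implied equilibrium (K = k_u/k_f) has dV_u = dV_act_u - dV_act_f and
    p_half equal to the crossing pressure, so data generated from this truth
    are thermodynamically/kinetically self-consistent by construction.
    """

    dV_act_f: float = datasets.DV_ACT_FOLD      # ml/mol
    dV_act_u: float = datasets.DV_ACT_UNFOLD    # ml/mol
    crossing_mpa: float = datasets.RATE_LINE_CROSSING_MPA
    k_at_crossing: float = 0.005                # s^-1; k_obs there is twice this
    T: float = DEFAULT_T

    @property
    def ln_kf0(self) -> float:
        return math.log(self.k_at_crossing) + self.dV_act_f * self.crossing_mpa / rt(self.T)

    @property
    def ln_ku0(self) -> float:
        return math.log(self.k_at_crossing) + self.dV_act_u * self.crossing_mpa / rt(self.T)

    def k_f(self, p: float) -> float:
        return math.exp(self.ln_kf0 - self.dV_act_f * p / rt(self.T))

    def k_u(self, p: float) -> float:
        return math.exp(self.ln_ku0 - self.dV_act_u * p / rt(self.T))

    def k_obs(self, p: float) -> float:
        return self.k_f(p) + self.k_u(p)

    @property
    def implied_equilibrium(self) -> CycleTruth:
        dV = self.dV_act_u - self.dV_act_f
        dG0 = rt(self.T) * (self.ln_kf0 - self.ln_ku0) / KJ_TO_J
        return CycleTruth(dG0_u=dG0, dV_u=dV)


@dataclass(frozen=True)
class SECTruth:
    """Calibration line and peak shape for synthetic chromatograms."""

    intercept: float = 5.6   # log10(mass) at K_av = 0
    slope: float = -2.0      # d log10(mass) / d K_av
    V0: float = datasets.SEC_V0_ML
    Vt: float = datasets.SEC_VT_ML
    peak_width_ml: float = 0.35

    def ve_of_mass(self, mass_da: float) -> float:
        kav = (math.log10(mass_da) - self.intercept) / self.slope
        return self.V0 + kav * (self.Vt - self.V0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full ground-truth description of the simulated two-cycle experiment.

    Cycle 1 is the substrate-bound dimer; cycle 2 (and the first
    decompression) is the post-dissociation, monomer-like species. Spectral
    bands are Gaussian in wavelength; their centers are calibrated at
    construction time so that the noiseless csm of the pure states equals the
    configured endpoint values on the configured grid.
    """

    T: float = DEFAULT_T
    # spectral truth (tryptophan channel)
    csm_folded_nm: float = datasets.CSM_FOLDED_NM
    csm_unfolded_nm: float = datasets.CSM_UNFOLDED_NM
    bandwidth_nm: float = 25.0
    amplitude: float = 100.0
    quantum_yield_ratio: float = 0.6   # unfolded/folded; < 1 emulates quenching
    wl_min: float = 300.0
    wl_max: float = 400.0
    wl_step: float = 1.0
    lambda_ref: float = datasets.LAMBDA_REF_NM
    # equilibrium truths per cycle
    cycle1: CycleTruth = CycleTruth(dG0_u=57.56, dV_u=-172.60)   # substrate-bound dimer
    cycle2: CycleTruth = CycleTruth(dG0_u=12.63, dV_u=-95.71)    # post-dissociation form
    # kinetic truth (applies to the monomer-like relaxations)
    kinetics: KineticTruth = KineticTruth()
    # SEC truth
    sec: SECTruth = SECTruth()
    # noise (relative Gaussian sd) and seed
    noise: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.noise < 0:
            raise ValidationError("noise must be non-negative")
        if self.bandwidth_nm <= 0:
            raise ValidationError("bandwidth must be positive")
        if self.amplitude <= 0 or self.quantum_yield_ratio <= 0:
            raise ValidationError("amplitudes must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_max - self.wl_min) / self.wl_step)) + 1
        return self.wl_min + self.wl_step * np.arange(n)

    def cycle_truth(self, cycle: int, branch: Branch) -> CycleTruth:
        """Cycle-1 compression keeps the native truth; everything after the
        first excursion to high pressure follows the cycle-2 truth."""
        if cycle == 1 and branch == "increasing":
            return self.cycle1
        return self.cycle2

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def _band(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _csm_nm_of_band(center: float, sigma: float, wl: np.ndarray) -> float:
    it = _band(wl, center, sigma)
    nu = wavelength_to_wavenumber(wl)
    return 1.0e7 / float(np.dot(nu, it) / np.sum(it))


_center_cache: dict[tuple, float] = {}


def _center_for_csm(target_nm: float, sigma: float, wl: np.ndarray) -> float:
    """Band center whose intensity-weighted csm equals ``target_nm``.

    The csm of a band that is Gaussian on the wavelength axis sits below the
    band center (the 1/lambda weighting is convex), so the center is solved
    for numerically once per (target, sigma, grid) and cached.
    """
    key = (target_nm, sigma, float(wl[0]), float(wl[-1]), len(wl))
    if key not in _center_cache:
        f = lambda c: _csm_nm_of_band(c, sigma, wl) - target_nm
        _center_cache[key] = brentq(f, target_nm - 5.0, target_nm + 20.0, xtol=1e-10)
    return _center_cache[key]


def band_centers(config: ScenarioConfig) -> tuple[float, float]:
    """Calibrated folded/unfolded band centers (nm) for this config."""
    wl = config.wavelengths
    return (
        _center_for_csm(config.csm_folded_nm, config.bandwidth_nm, wl),
        _center_for_csm(config.csm_unfolded_nm, config.bandwidth_nm, wl),
    )


def state_intensities_at(config: ScenarioConfig, lambda_nm: Optional[float] = None):
    """Noiseless pure-state intensities (folded, unfolded) at a wavelength."""
    lam = config.lambda_ref if lambda_nm is None else lambda_nm
    c_f, c_u = band_centers(config)
    s = config.bandwidth_nm
    obs_f = config.amplitude * math.exp(-0.5 * ((lam - c_f) / s) ** 2)
    obs_u = config.amplitude * config.quantum_yield_ratio * math.exp(
        -0.5 * ((lam - c_u) / s) ** 2
    )
    return obs_f, obs_u


def simulate_spectrum(
    f_u: float,
    config: ScenarioConfig,
    pressure: float = 0.1,
    rng: Optional[np.random.Generator] = None,
) -> Spectrum:
    """One emission spectrum at unfolded fraction ``f_u``.

    intensity(lambda) = A[(1-f_u) G(lambda; c_f, s) + f_u q G(lambda; c_u, s)]
    plus Gaussian noise of sd = noise * A, clipped at zero. The csm of the
    noiseless spectrum increases strictly with f_u.
    """
    if not 0.0 <= f_u <= 1.0:
        raise ValidationError("f_u must lie in [0, 1]")
    wl = config.wavelengths
    c_f, c_u = band_centers(config)
    s = config.bandwidth_nm
    clean = config.amplitude * (
        (1.0 - f_u) * _band(wl, c_f, s)
        + f_u * config.quantum_yield_ratio * _band(wl, c_u, s)
    )
    if config.noise > 0:
        if rng is None:
            rng = config.rng()
        clean = clean + config.noise * config.amplitude * rng.standard_normal(wl.size)
    return Spectrum(
        wavelengths=wl, intensities=np.clip(clean, 0.0, None), pressure=pressure
    )


def simulate_pressure_series(
    pressures: Sequence[float],
    config: ScenarioConfig,
    branch: Branch = "increasing",
    cycle: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> list[Spectrum]:
    """A spectrum per pressure; f_u(p) from the cycle's equilibrium truth."""
    truth = config.cycle_truth(cycle, branch)
    if rng is None:
        rng = config.rng(salt=1000 * cycle + (0 if branch == "increasing" else 1))
    return [
        simulate_spectrum(
            float(fraction_unfolded(truth.dG0_u, truth.dV_u, p, config.T)),
            config,
            pressure=p,
            rng=rng,
        )
        for p in pressures
    ]


def simulate_profile(
    pressures: Sequence[float],
    truth: CycleTruth,
    obs_f: float,
    obs_u: float,
    noise: float,
    rng: np.random.Generator,
    observable: str = "intensity",
    branch: Branch = "increasing",
    T: float = DEFAULT_T,
    lambda_ref: Optional[float] = None,
) -> PressureProfile:
    """Two-state profile generated directly at the observable level.

    Noise is homoscedastic Gaussian with sd = noise * |obs_f - obs_u|
    (relative to the transition amplitude).
    """
    p = np.asarray(pressures, dtype=float)
    y = predicted_observable(truth.dG0_u, truth.dV_u, obs_f, obs_u, p, T)
    if noise > 0:
        y = y + noise * abs(obs_f - obs_u) * rng.standard_normal(p.size)
    return PressureProfile(
        pressures=p, values=y, observable=observable, branch=branch,
        lambda_ref=lambda_ref if observable == "intensity" else None,
    )


def simulate_pjump_trace(
    p_final: float,
    config: ScenarioConfig,
    cycle: int = 2,
    p_initial: Optional[float] = None,
    n_samples: int = 400,
    span_factor: float = 5.0,
    dead_time: float = DEFAULT_DEAD_TIME,
    biexponential: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> RelaxationTrace:
    """Relaxation trace after a pressure jump (downward by 40 MPa by default).

    Rates come from the kinetic truth's log-linear laws at the final
    pressure; the intensity relaxes mono-exponentially with
    k_obs = k_f + k_u from the equilibrium intensity at the initial pressure
    toward that at the final pressure. Samples start at the dead time and
    span ``span_factor``/k_obs. ``biexponential`` adds a slow small-amplitude
    phase emulating the complex first-cycle upward jumps.
    """
    if p_initial is None:
        p_initial = p_final + 40.0
    kt = config.kinetics
    k_obs = kt.k_obs(p_final)
    eq = kt.implied_equilibrium
    obs_f, obs_u = state_intensities_at(config)
    I_eq = lambda p: float(
        predicted_observable(eq.dG0_u, eq.dV_u, obs_f, obs_u, p, config.T)
    )
    I_inf, I_start = I_eq(p_final), I_eq(p_initial)

    times = dead_time + np.linspace(0.0, span_factor / k_obs, n_samples)
    amp = I_start - I_inf
    clean = I_inf + amp * np.exp(-k_obs * times)
    if biexponential:
        clean = clean + 0.3 * amp * np.exp(-(k_obs / 50.0) * times)
    if config.noise > 0:
        if rng is None:
            rng = config.rng(salt=int(round(10 * p_final)) + 7_000_000 * cycle)
        clean = clean + config.noise * abs(amp) * rng.standard_normal(times.size)
    return RelaxationTrace(
        times=times,
        intensities=clean,
        p_initial=float(p_initial),
        p_final=float(p_final),
        cycle=cycle,
        dead_time=dead_time,
    )


DEFAULT_EQ_PRESSURES = np.concatenate([[0.1], np.arange(30.0, 601.0, 30.0)])  # 21 pts
DEFAULT_JUMP_FINAL_PRESSURES = np.arange(60.0, 341.0, 40.0)  # 8 finals, 60-340 MPa


@dataclass
class SimulatedExperiment:
    """In-memory twin of the full two-cycle pressurization experiment."""

    config: ScenarioConfig
    series: dict = field(default_factory=dict)   # (cycle, branch) -> list[Spectrum]
    traces: list = field(default_factory=list)   # RelaxationTrace, downward jumps


def simulate_two_cycle_experiment(
    config: Optional[ScenarioConfig] = None,
    eq_pressures: Optional[Sequence[float]] = None,
    jump_pressures: Optional[Sequence[float]] = None,
    replicates_per_jump: int = 1,
) -> SimulatedExperiment:
    """Generate spectra for both branches of two pressurization cycles plus
    downward-jump relaxation traces for each cycle.

    Branch/cycle truth mapping: the cycle-1 increasing branch uses the
    substrate-bound truth; the cycle-1 decreasing branch and both cycle-2
    branches use the post-dissociation truth (the hysteresis is a property of
    the data, not of the analysis).
    """
    cfg = config or ScenarioConfig()
    p_up = np.asarray(
        DEFAULT_EQ_PRESSURES if eq_pressures is None else eq_pressures, dtype=float
    )
    p_down = p_up[::-1]
    jumps = np.asarray(
        DEFAULT_JUMP_FINAL_PRESSURES if jump_pressures is None else jump_pressures,
        dtype=float,
    )

    exp = SimulatedExperiment(config=cfg)
    for cycle in (1, 2):
        exp.series[(cycle, "increasing")] = simulate_pressure_series(
            p_up, cfg, branch="increasing", cycle=cycle
        )
        exp.series[(cycle, "decreasing")] = simulate_pressure_series(
            p_down, cfg, branch="decreasing", cycle=cycle
        )
        for i_rep in range(replicates_per_jump):
            for pf in jumps:
                rng = cfg.rng(
                    salt=int(round(10 * pf)) + 7_000_000 * cycle + 131 * i_rep
                )
                exp.traces.append(
                    simulate_pjump_trace(float(pf), cfg, cycle=cycle, rng=rng)
                )
    return exp


def simulate_chromatogram(
    masses: Sequence[float],
    fractions: Sequence[float],
    sec_truth: Optional[SECTruth] = None,
    noise: float = 0.01,
    ve_noise_ml: float = 0.1,
    seed: int = 0,
    standards: Sequence[tuple] = datasets.SEC_STANDARD_MASSES,
    v_min: float = 9.0,
    v_max: float = 20.0,
    v_step: float = 0.02,
):
    """Synthetic elution profile plus a noisy standards table.

    Species elute at the volume the calibration-line truth predicts for their
    mass, as Gaussian peaks whose areas are proportional to ``fractions``.
    The chromatogram signal carries relative Gaussian noise of sd ``noise``
    (times the maximum signal); the standards' elution volumes carry absolute
    Gaussian noise of sd ``ve_noise_ml`` — instrument volume error is roughly
    constant in ml across a run, not proportional to Ve (0.1 ml is about 1%
    of a typical elution volume on this column).

    Returns (Chromatogram, list[Standard]).
    """
    truth = sec_truth or SECTruth()
    fr = np.asarray(fractions, dtype=float)
    if not math.isclose(float(fr.sum()), 1.0, rel_tol=1e-9):
        raise ValidationError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42]))

    v = np.arange(v_min, v_max + 0.5 * v_step, v_step)
    signal = np.zeros_like(v)
    w = truth.peak_width_ml
    for mass, f in zip(masses, fr):
        ve = truth.ve_of_mass(float(mass))
        signal += (f / (w * math.sqrt(2 * math.pi))) * np.exp(
            -0.5 * ((v - ve) / w) ** 2
        )
    if noise > 0:
        signal = signal + noise * float(np.max(signal)) * rng.standard_normal(v.size)
    chrom = Chromatogram(volumes=v, signal=np.clip(signal, 0.0, None))

    stds = []
    for name, mass in standards:
        ve = truth.ve_of_mass(float(mass))
        if ve_noise_ml > 0:
            ve = ve + ve_noise_ml * float(rng.standard_normal())
        stds.append(Standard(name=name, mass_da=float(mass), ve_ml=float(ve)))
    return chrom, stds


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    for key, cls in (("cycle1", CycleTruth), ("cycle2", CycleTruth),
                     ("kinetics", KineticTruth), ("sec", SECTruth)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    return ScenarioConfig(**d)


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    return replace(config, seed=seed)
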