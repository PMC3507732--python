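"""Size-exclusion chromatography: calibration, mass estimation, peak areas.

The partition coefficient K_av = (Ve - V0)/(Vt - V0) is linear in log10 of
molecular mass over a column's fractionation range; a straight-line
calibration against standards of known mass turns an elution volume into a
mass estimate. Elution profiles are decomposed as sums of Gaussian peaks, one
per oligomeric state, and peak areas give the state fractions.
"""

from __future__ import annotations

import itertools
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import t as t_dist

from barofold.errors import (
    FitFailureError,
    InsufficientDataError,
    ValidationError,
)


def compute_kav(Ve: float, V0: float, Vt: float) -> float:
    """Partition coefficient K_av = (Ve - V0)/(Vt - V0).

    Warns (does not fail) on values outside [0, 1]: inclusion/adsorption
    anomalies occur in practice.
    """
    if Vt <= V0:
        raise ValidationError("total volume must exceed void volume")
    kav = (Ve - V0) / (Vt - V0)
    if not -0.01 <= kav <= 1.01:
        _warnings.warn(
            f"K_av = {kav:.3f} outside [0, 1]: Ve = {Ve} ml not between V0 and Vt",
            stacklevel=2,
        )
    return float(kav)


class Standard(NamedTuple):
    name: str
    mass_da: float
    ve_ml: float


@dataclass
class SECCalibration:
    """Fitted calibration line log10(mass) = intercept + slope * K_av."""

    V0: float                 # ml
    Vt: float                 # ml
    standards: tuple          # of Standard
    slope: float              # expected negative
    intercept: float
    std_errors: dict = field(default_factory=dict)
    cov_ab: float = 0.0       # covariance(intercept, slope)
    dof: int = 0              # residual degrees of freedom of the line fit
    warnings: list = field(default_factory=list)

    @property
    def kav_range(self):
        k = [compute_kav(s.ve_ml, self.V0, self.Vt) for s in self.standards]
        return min(k), max(k)

    def predict_log10_mass(self, kav: float) -> float:
        return self.intercept + self.slope * kav

    def log10_mass_se(self, kav: float) -> float:
        """SE of the mean calibration-line response at one K_av."""
        va = self.std_errors.get("intercept", 0.0) ** 2
        vb = self.std_errors.get("slope", 0.0) ** 2
        return math.sqrt(max(va + kav**2 * vb + 2 * kav * self.cov_ab, 0.0))


def fit_calibration(
    standards: Sequence[Standard | tuple], V0: float, Vt: float
) -> SECCalibration:
    """Least-squares calibration line through the standards.

    A non-negative slope (mass increasing with K_av) indicates an inverted or
    unusable calibration and is flagged as a warning on the result.
    """
    stds = tuple(Standard(*s) for s in standards)
    if len(stds) < 3:
        raise InsufficientDataError("calibration needs >= 3 standards")
    if any(s.mass_da <= 0 for s in stds):
        raise ValidationError("standard masses must be positive")
    kav = np.array([compute_kav(s.ve_ml, V0, Vt) for s in stds])
    y = np.log10([s.mass_da for s in stds])

    n = len(stds)
    xm, ym = kav.mean(), y.mean()
    sxx = float(np.sum((kav - xm) ** 2))
    if sxx <= 0:
        raise ValidationError("standards elute at identical volumes")
    slope = float(np.sum((kav - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * kav)
    dof = n - 2
    s2 = float(np.sum(resid**2)) / dof if dof > 0 else math.nan
    se_slope = math.sqrt(s2 / sxx) if dof > 0 else math.nan
    se_intercept = math.sqrt(s2 * (1.0 / n + xm**2 / sxx)) if dof > 0 else math.nan
    cov_ab = -s2 * xm / sxx if dof > 0 else 0.0

    warns = []
    if slope >= 0:
        warns.append("calibration-inverted: slope of log10(mass) vs K_av is >= 0")
    return SECCalibration(
        V0=float(V0),
        Vt=float(Vt),
        standards=stds,
        slope=slope,
        intercept=intercept,
        std_errors={"slope": se_slope, "intercept": se_intercept},
        cov_ab=cov_ab,
        dof=dof,
        warnings=warns,
    )


@dataclass
class MassEstimate:
    """Molecular-mass estimate with a calibration-propagated interval."""

    mass_da: float
    lower_da: float       # 10^(pred - 2*SE)
    upper_da: float
    kav: float
    extrapolated: bool    # K_av outside the calibrated range

    def to_dict(self) -> dict:
        return {
            "mass_da": self.mass_da,
            "lower_da": self.lower_da,
            "upper_da": self.upper_da,
            "kav": self.kav,
            "extrapolated": self.extrapolated,
        }


def estimate_mass(Ve: float, cal: SECCalibration) -> MassEstimate:
    """Mass from an elution volume: 10^(a + b*K_av), interval from line SEs.

    The interval is a 95% confidence interval for the calibration-line
    response, 10^(prediction +/- t * SE) with the Student-t quantile at the
    line fit's residual degrees of freedom (calibration sets are small, so a
    Gaussian multiplier would undercover). Estimates outside the calibrated
    K_av range are flagged as extrapolated.
    """
    kav = compute_kav(Ve, cal.V0, cal.Vt)
    pred = cal.predict_log10_mass(kav)
    se = cal.log10_mass_se(kav)
    tq = float(t_dist.ppf(0.975, cal.dof)) if cal.dof > 0 else math.nan
    lo, hi = cal.kav_range
    return MassEstimate(
        mass_da=float(10.0**pred),
        lower_da=float(10.0 ** (pred - tq * se)),
        upper_da=float(10.0 ** (pred + tq * se)),
        kav=kav,
        extrapolated=bool(kav < lo - 1e-12 or kav > hi + 1e-12),
    )


@dataclass(frozen=True)
class Chromatogram:
    """An elution profile: signal vs elution volume."""

    volumes: np.ndarray   # ml, strictly increasing
    signal: np.ndarray    # non-negative

    def __post_init__(self):
        v = np.asarray(self.volumes, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "signal", s)
        if v.size != s.size:
            raise ValidationError("volumes and signal must have equal length")
        if v.size < 20:
            raise ValidationError("chromatogram needs >= 20 samples")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValidationError("volumes must be positive and strictly increasing")
        if np.any(s < 0):
            raise ValidationError("signal must be non-negative")


@dataclass
class GaussianPeak:
    center: float     # ml
    width: float      # ml (sigma)
    area: float
    fraction: float   # area / total area

    def to_dict(self) -> dict:
        return {
            "center_ml": self.center,
            "width_ml": self.width,
            "area": self.area,
            "fraction": self.fraction,
        }


def _pick_peak_centers(v: np.ndarray, s: np.ndarray, n_peaks: int) -> list[float]:
    """Centers of the n largest local maxima after 5-point smoothing.

    Smoothing is used for peak picking only, never for fitting. May return
    fewer than ``n_peaks`` centers when peaks overlap into shoulders; the
    missing ones are inserted from fit residuals later.
    """
    kernel = np.ones(5) / 5.0
    sm = np.convolve(s, kernel, mode="same")
    # prominence gate keeps noise bumps out of the candidate list
    idx, props = find_peaks(sm, prominence=0.05 * float(np.max(sm)))
    if idx.size == 0:
        idx = np.array([int(np.argmax(sm))])
        order = idx
    else:
        order = idx[np.argsort(props["prominences"])[::-1]]
    return [float(v[i]) for i in order[:n_peaks]]


def _fit_sum_of_gaussians(v, s, centers, width0, baseline):
    n = len(centers)
    span = float(v[-1] - v[0])

    def model(x, *theta):
        off = theta[-1] if baseline else 0.0
        y = np.full_like(x, off, dtype=float)
        for i in range(n):
            a, c, w = theta[3 * i : 3 * i + 3]
            y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
        return y

    p0, lo, hi = [], [], []
    for c in centers:
        amp0 = max(float(np.interp(c, v, s)), 1e-3 * float(np.max(s)))
        p0 += [amp0, c, width0]
        lo += [0.0, float(v[0]), 1e-4 * span]
        hi += [np.inf, float(v[-1]), span]
    if baseline:
        p0.append(0.0)
        lo.append(-np.inf)
        hi.append(np.inf)
    popt, _ = curve_fit(model, v, s, p0=p0, bounds=(lo, hi), maxfev=40000)
    return popt, model(v, *popt)


def decompose_chromatogram(
    chrom: Chromatogram, n_peaks: int, baseline: bool = False
) -> list[GaussianPeak]:
    """Least-squares sum-of-Gaussians decomposition of an elution profile.

    Returns peaks ordered by elution volume with fractions normalized to 1.
    Initialization: centers at the largest local maxima (after a 5-point
    moving average used for picking only), widths at 2% of the volume span.
    Overlapping peaks can hide as shoulders (fewer visible maxima than
    ``n_peaks``); the missing centers are then multi-started from several
    candidate placements (largest fit residual; offsets from the main peak)
    and the restart with the lowest residual sum of squares wins — a single
    start is prone to local minima at ~2-sigma peak separation. ``baseline``
    adds a constant offset term.
    """
    if n_peaks not in (1, 2, 3):
        raise ValidationError("n_peaks must be 1, 2 or 3")
    v, s = chrom.volumes, chrom.signal
    span = float(v[-1] - v[0])
    width0 = 0.02 * span
    visible = _pick_peak_centers(v, s, n_peaks)

    try:
        if len(visible) >= n_peaks:
            candidate_sets = [sorted(visible[:n_peaks])]
        else:
            popt1, yhat1 = _fit_sum_of_gaussians(v, s, visible, width0, baseline)
            c1, w1 = float(popt1[1]), float(popt1[2])
            pool = [
                float(v[int(np.argmax(s - yhat1))]),
                c1 - 1.5 * w1, c1 + 1.5 * w1,
                c1 - 0.8 * w1, c1 + 0.8 * w1,
            ]
            pool = [c for c in pool if v[0] < c < v[-1]]
            need = n_peaks - len(visible)
            candidate_sets = [
                sorted(visible + list(extra))
                for extra in itertools.combinations(pool, need)
            ]
        best: tuple[float, Optional[np.ndarray]] = (math.inf, None)
        last_err: Optional[Exception] = None
        for cand in candidate_sets:
            try:
                popt_c, yhat_c = _fit_sum_of_gaussians(v, s, cand, width0, baseline)
            except (RuntimeError, ValueError) as exc:
                last_err = exc
                continue
            sse = float(np.sum((s - yhat_c) ** 2))
            if sse < best[0]:
                best = (sse, popt_c)
        if best[1] is None:
            raise last_err or RuntimeError("no restart converged")
        popt = best[1]
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"chromatogram decomposition failed: {exc}",
            diagnostics={"n_peaks": n_peaks, "visible_centers": visible},
        ) from exc

    peaks = []
    for i in range(n_peaks):
        a, c, w = (float(x) for x in popt[3 * i : 3 * i + 3])
        area = a * w * math.sqrt(2.0 * math.pi)
        peaks.append(GaussianPeak(center=c, width=w, area=area, fraction=math.nan))
    total = sum(pk.area for pk in peaks)
    if total <= 0:
        raise FitFailureError("decomposition produced zero total area")
    w_min = min(pk.width for pk in peaks)
    for pk in peaks:
        pk.fraction = pk.area / total
        # oligomers on one column elute with comparable peak widths; a width
        # outlier or a vanishing area means n_peaks exceeds the data's support
        if (
            pk.width <= 2e-4 * span
            or pk.width >= 0.5 * span
            or pk.width > 3.0 * w_min
            or pk.fraction < 0.005
        ):
            _warnings.warn(
                f"degenerate peak at {pk.center:.2f} ml (sigma = {pk.width:.3g} ml, "
                f"fraction = {pk.fraction:.4f}); n_peaks may exceed the number of "
                "visible peaks",
                stacklevel=2,
            )
    peaks.sort(key=lambda pk: pk.center)
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b.center - a.center < max(a.width, b.width):
            _warnings.warn(
                f"width-degenerate split: peaks at {a.center:.2f} and {b.center:.2f} ml "
                "are closer than one peak width; n_peaks may exceed the number of "
                "visible peaks",
                stacklevel=2,
            )
    return peaks
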