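"""Emission spectra and the scalar observables derived from them.

Two observables drive the thermodynamic analysis:

* the center of spectral mass (csm), the intensity-weighted mean emission
  wavenumber  csm = sum(nu_i * F_i) / sum(F_i)  with nu_i = 1e7 / lambda_i,
  which reports the mean solvent exposure of the tryptophan residues; and
* the emission intensity at a fixed characteristic wavelength.

csm is computed in wavenumber space (cm^-1) and also reported on the
wavelength axis as 1e7 / csm_wavenumber — a harmonic-type conversion, not the
intensity-weighted mean over nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

from barofold.errors import (
    ExtrapolationError,
    InsufficientDataError,
    UndefinedObservableError,
    ValidationError,
)

Channel = Literal["tryptophan", "ANS"]
Branch = Literal["increasing", "decreasing"]
Observable = Literal["csm_nm", "csm_wavenumber", "intensity"]

NM_CM_FACTOR = 1.0e7  # nm * cm^-1 product for the lambda <-> nu conversion


def wavelength_to_wavenumber(lambda_nm):
    """Convert wavelength [nm] to wavenumber [cm^-1]: nu = 1e7 / lambda."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("wavelength must be positive (nm)")
    out = NM_CM_FACTOR / lam
    return float(out) if np.isscalar(lambda_nm) or out.ndim == 0 else out


def wavenumber_to_wavelength(nu_cm):
    """Convert wavenumber [cm^-1] to wavelength [nm]; involutive with the above."""
    nu = np.asarray(nu_cm, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("wavenumber must be positive (cm^-1)")
    out = NM_CM_FACTOR / nu
    return float(out) if np.isscalar(nu_cm) or out.ndim == 0 else out


@dataclass(frozen=True)
class Spectrum:
    """A sampled fluorescence emission spectrum at one pressure.

    wavelengths are strictly increasing, in nm; intensities are non-negative
    (arbitrary units) with positive total. A single-point spectrum is allowed
    only as a delta-spectrum fixture.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    pressure: float = 0.1  # MPa; 0.1 denotes atmospheric
    channel: Channel = "tryptophan"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValidationError("wavelengths and intensities must be 1-D of equal length")
        if wl.size < 1:
            raise ValidationError("empty spectrum")
        if np.any(wl <= 0):
            raise ValidationError("wavelengths must be positive")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValidationError("intensities must be non-negative")
        if not np.sum(it) > 0:
            raise ValidationError("total intensity must be positive")
        if self.pressure < 0:
            raise ValidationError("pressure must be non-negative (MPa)")
        if self.channel not in ("tryptophan", "ANS"):
            raise ValidationError(f"unknown channel {self.channel!r}")

    def __len__(self) -> int:
        return self.wavelengths.size


class CsmResult(NamedTuple):
    csm_wavenumber: float  # cm^-1
    csm_nm: float          # nm, = 1e7 / csm_wavenumber


def compute_csm(spectrum: Spectrum) -> CsmResult:
    """Center of spectral mass: intensity-weighted mean wavenumber.

    Returns the csm both in cm^-1 and on the wavelength axis. The result is
    invariant under uniform intensity scaling and lies between the extreme
    wavenumbers of the support.
    """
    total = float(np.sum(spectrum.intensities))
    if total <= 0:  # pragma: no cover - blocked by the Spectrum invariant
        raise UndefinedObservableError("csm undefined for zero total intensity")
    nu = wavelength_to_wavenumber(spectrum.wavelengths)
    csm_nu = float(np.dot(np.atleast_1d(nu), spectrum.intensities) / total)
    return CsmResult(csm_nu, NM_CM_FACTOR / csm_nu)


def intensity_at(spectrum: Spectrum, lambda_nm: float) -> float:
    """Emission intensity at a wavelength, linearly interpolated on the grid.

    Exact grid points return the stored value; queries outside the grid raise
    (no extrapolation).
    """
    wl = spectrum.wavelengths
    if lambda_nm < wl[0] or lambda_nm > wl[-1]:
        raise ExtrapolationError(
            f"{lambda_nm} nm outside the sampled grid [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(lambda_nm, wl, spectrum.intensities))


@dataclass(frozen=True)
class PressureProfile:
    """One branch of a pressure titration: (pressure, observable) points."""

    pressures: np.ndarray             # MPa, strictly monotone per branch
    values: np.ndarray
    observable: Observable
    branch: Branch
    cycle: int = 1
    channel: Channel = "tryptophan"
    lambda_ref: Optional[float] = None  # nm, set when observable == "intensity"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        p = np.asarray(self.pressures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "values", v)
        if p.size != v.size:
            raise ValidationError("pressures and values must have equal length")
        if self.cycle < 1:
            raise ValidationError("cycle must be a positive integer")
        d = np.diff(p)
        if self.branch == "increasing":
            if np.any(d <= 0):
                raise ValidationError("pressures not strictly increasing on an increasing branch")
        elif self.branch == "decreasing":
            if np.any(d >= 0):
                raise ValidationError("pressures not strictly decreasing on a decreasing branch")
        else:
            raise ValidationError(f"unknown branch {self.branch!r}")

    def __len__(self) -> int:
        return self.pressures.size

    def require_fittable(self) -> None:
        if len(self) < 5:
            raise InsufficientDataError(
                f"two-state fitting requires >= 5 points, got {len(self)}"
            )


def build_profile(
    series: Sequence[Spectrum],
    observable: Observable,
    lambda_ref: Optional[float] = None,
    cycle: int = 1,
) -> PressureProfile:
    """Assemble a PressureProfile from an acquisition-ordered spectrum series.

    The branch is inferred from the pressure ordering; a non-monotone pressure
    sequence is ambiguous and rejected. ``lambda_ref`` is required for (and
    only for) the intensity observable.
    """
    if len(series) < 2:
        raise InsufficientDataError("need at least two spectra to build a profile")
    channels = {s.channel for s in series}
    if len(channels) > 1:
        raise ValidationError(f"mixed channels in series: {sorted(channels)}")
    if observable == "intensity":
        if lambda_ref is None:
            raise ValidationError("lambda_ref is required for the intensity observable")
    elif lambda_ref is not None:
        raise ValidationError("lambda_ref only applies to the intensity observable")

    pressures = np.array([s.pressure for s in series], dtype=float)
    d = np.diff(pressures)
    if np.all(d > 0):
        branch: Branch = "increasing"
    elif np.all(d < 0):
        branch = "decreasing"
    else:
        raise ValidationError("pressures are not monotone; branch is ambiguous")

    if observable == "intensity":
        values = np.array([intensity_at(s, lambda_ref) for s in series])
    elif observable == "csm_nm":
        values = np.array([compute_csm(s).csm_nm for s in series])
    elif observable == "csm_wavenumber":
        values = np.array([compute_csm(s).csm_wavenumber for s in series])
    else:
        raise ValidationError(f"unknown observable {observable!r}")

    return PressureProfile(
        pressures=pressures,
        values=values,
        observable=observable,
        branch=branch,
        cycle=cycle,
        channel=series[0].channel,
        lambda_ref=lambda_ref,
    )
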