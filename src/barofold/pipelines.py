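"""Orchestration: full equilibrium and kinetics analyses over a dataset.

These drivers reproduce the two analysis workflows end to end: per
branch/cycle two-state fits with hysteresis comparison, and per-trace
relaxation fits decomposed into folding/unfolding rate constants with
activation volumes and the thermodynamic-kinetic consistency check. Reports
are plain dicts (JSON-ready, deterministic given identical inputs).
"""

from __future__ import annotations

import logging
import time
from typing import Optional, Sequence

from barofold import __version__
from barofold.equilibrium import TwoStateFit, compare_branches, fit_two_state
from barofold.errors import BarofoldError, InsufficientDataError, ValidationError
from barofold.kinetics import (
    RelaxationTrace,
    consistency_check,
    decompose_rates,
    fit_activation_volumes,
    fit_monoexponential,
    kobs_minimum_pressure,
)
from barofold.spectra import build_profile
from barofold.units import DEFAULT_T

log = logging.getLogger("barofold")


def run_equilibrium_pipeline(
    series: dict,
    T: float = DEFAULT_T,
    observables: Sequence[str] = ("csm_nm", "intensity"),
    lambda_ref: float = 338.0,
) -> dict:
    """Fit every (cycle, branch) spectrum series with the two-state model.

    ``series`` maps (cycle, branch) to an acquisition-ordered list of
    Spectrum. Returns a report with one fit per (cycle, branch, observable)
    and a hysteresis comparison per (cycle, observable) where both branches
    are present; stage failures are recorded per key, not raised.
    """
    if not series:
        raise ValidationError("empty dataset: no spectrum series")
    t0 = time.time()
    fits: dict = {}
    report: dict = {"software_version": __version__, "T_K": T, "fits": {}, "hysteresis": {}}
    for (cycle, branch), spectra in sorted(series.items()):
        for obs in observables:
            key = f"cycle{cycle}_{branch}_{obs}"
            try:
                prof = build_profile(
                    spectra, obs, lambda_ref=lambda_ref if obs == "intensity" else None,
                    cycle=cycle,
                )
                fit = fit_two_state(prof, T=T)
                fits[(cycle, branch, obs)] = fit
                report["fits"][key] = fit.to_dict()
            except BarofoldError as exc:
                report["fits"][key] = {"status": "failed", "error": str(exc)}
                log.warning("equilibrium fit %s failed: %s", key, exc)

    cycles = sorted({c for (c, _b) in series})
    for cycle in cycles:
        for obs in observables:
            up = fits.get((cycle, "increasing", obs))
            down = fits.get((cycle, "decreasing", obs))
            key = f"cycle{cycle}_{obs}"
            if up is None or down is None:
                report["hysteresis"][key] = {"status": "skipped: single branch"}
                continue
            report["hysteresis"][key] = compare_branches(up, down).to_dict()
    report["elapsed_s"] = round(time.time() - t0, 3)
    report["_fits"] = fits  # live objects for downstream use
    return report


def run_kinetics_pipeline(
    traces: Sequence[RelaxationTrace],
    eq: TwoStateFit,
    T: float = DEFAULT_T,
    cycle: Optional[int] = None,
    direction: str = "downward",
) -> dict:
    """Relaxation fits, rate decomposition and activation volumes.

    Uses ``eq`` (the chosen equilibrium parameter set — which cycle/branch
    supplies K(p) is an explicit caller decision) to split each fitted k_obs
    into k_f and k_u, then fits the log-linear rate laws. Defaults to
    downward jumps, the regime where the relaxation is single-exponential.
    """
    t0 = time.time()
    selected = [
        tr for tr in traces
        if (cycle is None or tr.cycle == cycle) and tr.direction == direction
    ]
    finals = {tr.p_final for tr in selected}
    if len(finals) < 3:
        raise InsufficientDataError(
            f"need traces at >= 3 distinct final pressures, got {len(finals)}"
        )
    if cycle is not None and eq.profile is not None and eq.profile.cycle != cycle:
        log.warning(
            "equilibrium fit comes from cycle %s but jumps are from cycle %s",
            eq.profile.cycle, cycle,
        )

    report: dict = {"software_version": __version__, "T_K": T, "traces": [], "status": "ok"}
    decomps = []
    for tr in selected:
        entry = {"p_initial_MPa": tr.p_initial, "p_final_MPa": tr.p_final, "cycle": tr.cycle}
        try:
            kin = fit_monoexponential(tr)
            dec = decompose_rates(kin.k_obs, tr.p_final, eq, T)
            decomps.append(dec)
            entry.update(kin.to_dict())
            entry.update({"k_f_per_s": dec.k_f, "k_u_per_s": dec.k_u, "K_p": dec.K_p})
        except BarofoldError as exc:
            entry.update({"status": "failed", "error": str(exc)})
            report["status"] = "partial"
        report["traces"].append(entry)

    act = fit_activation_volumes(decomps, T=T)
    report["activation_volumes"] = act.to_dict()
    report["consistency"] = consistency_check(act, eq).to_dict()
    try:
        report["kobs_minimum_MPa"] = kobs_minimum_pressure(act)
        report["dip_minus_crossing_MPa"] = (
            report["kobs_minimum_MPa"] - act.crossing_pressure
        )
    except ValidationError:
        report["kobs_minimum_MPa"] = None
    report["eq_source"] = eq.to_dict()
    report["elapsed_s"] = round(time.time() - t0, 3)
    report["_activation_volumes"] = act
    report["_decompositions"] = decomps
    return report
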