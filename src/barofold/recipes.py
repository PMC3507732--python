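"""Self-contained study recipes at the published conditions.

Each recipe regenerates synthetic data at the conditions of the original
experiments (pressure ladders, noise levels, replicate counts, published
ground-truth parameters), runs the corresponding analysis end to end and
returns summary numbers. They power the acceptance checks and the analysis
drivers; every stochastic draw descends from the ``base_seed`` argument.
"""

from __future__ import annotations

import numpy as np

from barofold import datasets
from barofold.equilibrium import TwoStateFit, fit_two_state, half_transition_pressure
from barofold.kinetics import (
    consistency_check,
    decompose_rates,
    fit_activation_volumes,
    fit_monoexponential,
    kobs_minimum_pressure,
)
from barofold.sec import decompose_chromatogram, estimate_mass, fit_calibration
from barofold.synthetic import (
    CycleTruth,
    DEFAULT_EQ_PRESSURES,
    DEFAULT_JUMP_FINAL_PRESSURES,
    ScenarioConfig,
    simulate_chromatogram,
    simulate_pjump_trace,
    simulate_profile,
    state_intensities_at,
)
from barofold.units import DEFAULT_T


def table_phalf_consistency() -> list[dict]:
    """Check p_half = -1000*dG0/dV against every published table row.

    High-precision rows (printed with 2 decimals) must agree to the printed
    precision; integer-rounded rows to max(1%, 2 MPa).
    """
    out = []
    for row in datasets.TABLE_UNFOLDING:
        computed = half_transition_pressure(TwoStateFit(row.dG0_u, row.dV_u))
        if row.exact_printed:
            tol = 0.005  # agree to the printed 2-decimal precision
        else:
            tol = max(0.01 * row.p_half_printed, 2.0)
        out.append(
            {
                "protein": row.protein,
                "ligand": row.ligand,
                "branch": row.branch,
                "observable": row.observable,
                "p_half_computed_MPa": computed,
                "p_half_printed_MPa": row.p_half_printed,
                "abs_dev_MPa": abs(computed - row.p_half_printed),
                "tolerance_MPa": tol,
                "consistent": abs(computed - row.p_half_printed) <= tol,
            }
        )
    return out


def equilibrium_recovery_study(
    n_seeds: int = 50,
    noise: float = 0.01,
    base_seed: int = 1,
    truth: CycleTruth = CycleTruth(8.37, -34.18),
) -> dict:
    """Recover dV_u from noisy intensity profiles at the published dimer truth.

    21-point pressure ladder (0.1 then 30 MPa steps to 600), homoscedastic
    noise relative to the transition amplitude. Reports the median recovered
    dV_u and the fraction of seeds whose 1-SE interval covers the truth
    (nominal 68%).
    """
    cfg = ScenarioConfig()
    obs_f, obs_u = state_intensities_at(cfg)
    dvs, ses, covered = [], [], 0
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, i]))
        prof = simulate_profile(DEFAULT_EQ_PRESSURES, truth, obs_f, obs_u, noise, rng)
        fit = fit_two_state(prof)
        dvs.append(fit.dV_u)
        ses.append(fit.std_errors["dV_u"])
        if abs(fit.dV_u - truth.dV_u) <= fit.std_errors["dV_u"]:
            covered += 1
    median_dv = float(np.median(dvs))
    return {
        "truth_dV_ml_mol": truth.dV_u,
        "median_dV_ml_mol": median_dv,
        "median_dV_rel_err": abs(median_dv - truth.dV_u) / abs(truth.dV_u),
        "se_coverage_68": covered / n_seeds,
        "n_seeds": n_seeds,
    }


def kinetics_recovery_study(
    n_reps: int = 50,
    noise: float = 0.02,
    replicates_per_pressure: int = 3,
    base_seed: int = 1,
    T: float = DEFAULT_T,
) -> dict:
    """End-to-end activation-volume recovery from simulated downward jumps.

    Eight final pressures spanning 60-340 MPa, ground truth
    dV_act_f = +95 ml/mol and dV_act_u = -5.5 ml/mol (the published values),
    mono-exponential traces with 2% amplitude-relative noise. A repetition
    succeeds when both fitted activation volumes land within the published
    uncertainties (8 and 0.7 ml/mol). Also verifies k_f + k_u = k_obs to
    machine precision at every decomposition.
    """
    ok = 0
    last = None
    max_sum_err = 0.0
    dvfs, dvus = [], []
    for rep in range(n_reps):
        cfg = ScenarioConfig(noise=noise, seed=int(base_seed) * 100_003 + rep)
        eq = cfg.kinetics.implied_equilibrium.as_fit(*state_intensities_at(cfg), T=T)
        decs = []
        for i_rep in range(replicates_per_pressure):
            for pf in DEFAULT_JUMP_FINAL_PRESSURES:
                rng = cfg.rng(salt=int(round(10 * pf)) + 1009 * i_rep)
                tr = simulate_pjump_trace(float(pf), cfg, rng=rng)
                kin = fit_monoexponential(tr)
                dec = decompose_rates(kin.k_obs, float(pf), eq, T)
                max_sum_err = max(max_sum_err, abs(dec.k_f + dec.k_u - kin.k_obs))
                decs.append(dec)
        act = fit_activation_volumes(decs, T=T)
        dvfs.append(act.dV_act_f)
        dvus.append(act.dV_act_u)
        last = act
        if (
            abs(act.dV_act_f - datasets.DV_ACT_FOLD) <= datasets.DV_ACT_FOLD_SE
            and abs(act.dV_act_u - datasets.DV_ACT_UNFOLD) <= datasets.DV_ACT_UNFOLD_SE
        ):
            ok += 1
    return {
        "success_rate": ok / n_reps,
        "median_dV_act_f_ml_mol": float(np.median(dvfs)),
        "median_dV_act_u_ml_mol": float(np.median(dvus)),
        "max_rate_sum_error": max_sum_err,
        "n_reps": n_reps,
        "last_fit": last,
    }


def dip_study(noise: float = 0.02, base_seed: int = 1, T: float = DEFAULT_T) -> dict:
    """Locate the minimum of the reconstructed k_obs(p) and the line crossing.

    For log-linear rate laws the minimum sits at
    p_cross + RT*ln(|s_f|/|s_u|)/(|s_f|+|s_u|); with strongly asymmetric
    activation volumes it is therefore displaced well above the crossing.
    """
    cfg = ScenarioConfig(noise=noise, seed=base_seed)
    eq = cfg.kinetics.implied_equilibrium.as_fit(*state_intensities_at(cfg), T=T)
    decs = []
    for pf in DEFAULT_JUMP_FINAL_PRESSURES:
        tr = simulate_pjump_trace(float(pf), cfg)
        decs.append(decompose_rates(fit_monoexponential(tr).k_obs, float(pf), eq, T))
    act = fit_activation_volumes(decs, T=T)
    p_min = kobs_minimum_pressure(act)
    return {
        "crossing_MPa": act.crossing_pressure,
        "kobs_minimum_MPa": p_min,
        "dip_minus_crossing_MPa": p_min - act.crossing_pressure,
        "activation_volumes": act,
    }


def identity_study(base_seed: int = 1, T: float = DEFAULT_T) -> dict:
    """Thermodynamic-kinetic identity dV_u = dV_act_u - dV_act_f.

    Runs the full kinetic pipeline on self-consistently generated noiseless
    data and compares the implied dV_u with the generating equilibrium truth;
    also evaluates the identity at the published activation volumes.
    """
    cfg = ScenarioConfig(noise=0.0, seed=base_seed)
    eq_truth = cfg.kinetics.implied_equilibrium
    eq = eq_truth.as_fit(*state_intensities_at(cfg), T=T)
    decs = []
    for pf in DEFAULT_JUMP_FINAL_PRESSURES:
        tr = simulate_pjump_trace(float(pf), cfg)
        decs.append(decompose_rates(fit_monoexponential(tr).k_obs, float(pf), eq, T))
    act = fit_activation_volumes(decs, T=T)
    rep = consistency_check(act, eq)
    return {
        "implied_dV_u_ml_mol": rep.implied_dV_u,
        "generating_dV_u_ml_mol": eq_truth.dV_u,
        "difference_ml_mol": rep.implied_dV_u - eq_truth.dV_u,
        "published_identity_ml_mol": datasets.DV_ACT_UNFOLD - datasets.DV_ACT_FOLD,
        "consistent": rep.consistent,
    }


def sec_roundtrip_study(
    n_seeds: int = 50,
    noise: float = 0.01,
    base_seed: int = 1,
    fractions: tuple = (0.85, 0.15),
) -> dict:
    """Dimer/monomer chromatogram round trip at the published masses.

    Generates 34.8 kDa : 18.97 kDa mixtures at the given fractions with 1%
    signal noise, decomposes into two Gaussians and estimates both masses
    from a freshly fitted calibration each seed. Reports the rate of seeds
    with all fractions within 3 percentage points, and the rate with both
    true masses inside the propagated 95% intervals.
    """
    masses = (datasets.SEC_DIMER_MASS_DA, datasets.SEC_MONOMER_MASS_DA)
    frac_ok = mass_ok = 0
    est_fracs, est_masses = [], []
    for i in range(n_seeds):
        seed = int(base_seed) * 100_003 + i
        chrom, stds = simulate_chromatogram(masses, fractions, noise=noise, seed=seed)
        cal = fit_calibration(stds, datasets.SEC_V0_ML, datasets.SEC_VT_ML)
        peaks = decompose_chromatogram(chrom, 2)
        est_fracs.append([pk.fraction for pk in peaks])
        ests = [estimate_mass(pk.center, cal) for pk in peaks]
        est_masses.append([e.mass_da for e in ests])
        if all(abs(pk.fraction - f) <= 0.03 for pk, f in zip(peaks, fractions)):
            frac_ok += 1
        if all(e.lower_da <= m <= e.upper_da for e, m in zip(ests, masses)):
            mass_ok += 1
    med_fracs = np.median(est_fracs, axis=0)
    med_masses = np.median(est_masses, axis=0)
    return {
        "fraction_ok_rate": frac_ok / n_seeds,
        "mass_in_interval_rate": mass_ok / n_seeds,
        "median_fractions": [float(x) for x in med_fracs],
        "median_masses_da": [float(x) for x in med_masses],
        "n_seeds": n_seeds,
    }
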