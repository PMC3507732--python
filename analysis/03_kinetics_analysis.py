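#!/usr/bin/env python
"""Pressure-jump relaxation kinetics.

Fits the simulated downward-jump traces, decomposes k_obs into folding and
unfolding rate constants with the self-consistent equilibrium, fits the
log-linear rate laws for the activation volumes, and evaluates the
thermodynamic-kinetic identity plus the position of the k_obs dip relative
to the rate-line crossing. Tables go to results/kinetics/.
"""

from pathlib import Path

import pandas as pd

from barofold import recipes
from barofold.io import load_experiment
from barofold.pipelines import run_kinetics_pipeline
from barofold.synthetic import ScenarioConfig, state_intensities_at

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "kinetics"
SEED = 20120913


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = ROOT / "synthetic_experiment"
    if not dataset.exists():
        raise SystemExit("run 01_simulate_experiment.py first")
    _, traces = load_experiment(dataset)

    cfg = ScenarioConfig(seed=SEED, noise=0.01)
    eq = cfg.kinetics.implied_equilibrium.as_fit(*state_intensities_at(cfg))
    rep = run_kinetics_pipeline(traces, eq, cycle=2)

    pd.DataFrame(
        [{k: v for k, v in t.items() if not isinstance(v, dict)} for t in rep["traces"]]
    ).to_csv(OUT / "trace_fits.csv", index=False)

    act = rep["activation_volumes"]
    print(f"activation volumes: dV_act_f = {act['dV_act_f_ml_mol']:.1f} "
          f"+/- {act['std_errors']['dV_act_f']:.1f} ml/mol, "
          f"dV_act_u = {act['dV_act_u_ml_mol']:.2f} "
          f"+/- {act['std_errors']['dV_act_u']:.2f} ml/mol")
    print(f"rate lines cross at {act['crossing_pressure_MPa']:.1f} MPa; "
          f"reconstructed k_obs dips at {rep['kobs_minimum_MPa']:.1f} MPa "
          f"({rep['dip_minus_crossing_MPa']:+.1f} MPa from the crossing)")
    cons = rep["consistency"]
    print(f"identity dV_act_u - dV_act_f = {cons['implied_dV_u_ml_mol']:.1f} ml/mol "
          f"vs equilibrium dV_u = {cons['eq_dV_u_ml_mol']:.1f} "
          f"(consistent: {cons['consistent']})")

    summary = {k: v for k, v in rep.items() if not k.startswith("_") and k != "traces"}
    pd.json_normalize(summary).to_csv(OUT / "summary.csv", index=False)

    # recovery study at the published activation volumes
    rec = recipes.kinetics_recovery_study(n_reps=50, base_seed=SEED)
    pd.DataFrame([{k: v for k, v in rec.items() if k != "last_fit"}]).to_csv(
        OUT / "recovery.csv", index=False
    )
    print(f"recovery over {rec['n_reps']} repetitions: both activation volumes "
          f"within the published uncertainties in {rec['success_rate']:.0%}")


if __name__ == "__main__":
    main()
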