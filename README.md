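# cardiofit

Multi-objective parameter fitting for cardiac cellular electrophysiology
models that captures **both** cellular and intercellular properties: the
action-potential (AP) waveform *and* the voltage-resolved membrane
resistance (R_m) profile.

## Why

R_m = ΔV_m/ΔI_m is the slope resistance of the myocyte membrane. It controls
how strongly a cell loads its neighbours in tissue — conduction velocity,
source–sink safety, early after-depolarization risk — yet classical
AP-only fitting leaves it unconstrained: parameter sets with nearly
identical APs can have wildly different R_m. cardiofit measures R_m along
the AP with a dual voltage-clamp protocol (hold at v ± 10 mV for 5 ms,
R_m = 20 mV / ΔI_m, normalized to 180 pF), detects the voltages where ΔI_m
changes sign and R_m diverges (the borders of the all-or-none-repolarization
window), excludes ±5 mV *disallowed regions* around them, and fits inside
the *allowed regions*:

* **f1 = RMSE_AP (mV)** — AP waveform error on a uniform time grid,
* **f2 = RMSE_Rc (GΩ)** — error of the interpolated R_m curve in Allowed
  Region 2 (late repolarization, which contains the negative-R_m window),
* **f3 = AE_Rd (GΩ)** — absolute error of the diastolic resistance in
  Allowed Region 3.

The 1–3-objective problem over 16 conductance/rate scale factors of the
ten Tusscher et al. (2004) epicardial model is solved with a from-scratch
elitist NSGA-II (population 100, 10 000 evaluations, SBX/polynomial
operators with distribution indices 20/20), and a knee-like preferred
solution is picked from the final Pareto front by the normalized-sum rule.
Reference "experimental" data are perturbed-TNNP configurations (baseline,
shortened/prolonged APD, hyper-/hypokalemia) with known ground truth.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
import numpy as np
from cardiofit import (StimulusProtocol, build_tnnp_model,
                       pace_to_steady_state, find_singularities,
                       define_regions, prepare_reference, run_trial)
from cardiofit.moea import NSGAConfig

# 1. pace the nominal TNNP epicardial model to steady state
model = build_tnnp_model()
protocol = StimulusProtocol()          # 20 pA/pF x 2 ms, 1 Hz, 20 beats
paced = pace_to_steady_state(model, protocol)
print(f"peak {paced.trace.vm.max():.1f} mV, rest {paced.trace.vm.min():.1f} mV")

# 2. locate the Rm singularities and build voltage regions
sing = find_singularities(model, protocol, 1.0, paced=paced)
regions = define_regions([sing], span_mV=(paced.trace.vm.min(),
                                          paced.trace.vm.max()))
print("singularities:", [f"{s:.1f}" for s in sing])
print("allowed region 2:", tuple(f"{v:.1f}" for v in regions.allowed_region(2)))

# 3. fit the base model to the shortened-APD reference (scaled down)
prot5 = StimulusProtocol(n_beats=5)
bundle = prepare_reference("shortened_apd", prot5)
trial = run_trial(2, "shortened_apd", seed=0,
                  optimizer_config=NSGAConfig(pop_size=20, max_evaluations=300),
                  protocol=prot5, bundle=bundle)
print(f"selected solution: RMSE_AP = {trial.f1_rmse_ap_mV:.3f} mV, "
      f"RMSE_Rc = {trial.f2_rmse_rc_GOhm:.4f} GOhm, "
      f"AE_Rd = {trial.f3_ae_rd_GOhm:.5f} GOhm")
```

Output:

```
peak 32.9 mV, rest -86.3 mV
singularities: ['-62.4', '-2.6']
allowed region 2: ('-57.4', '-7.6')
selected solution: RMSE_AP = 5.086 mV, RMSE_Rc = 0.0150 GOhm, AE_Rd = 0.00013 GOhm
```

Reading this: the nominal epicardial AP spans −86.3…+32.9 mV; its R_m
profile diverges at −62.4 and −2.6 mV, which bound the negative-R_m window,
so the fitted R_m curve lives on (−57.4, −7.6) mV. The bi-objective fit
(scenario 2, 20×15 budget) returns a compromise solution whose R_m curve
error is 0.015 GΩ at the cost of a 5.1 mV AP error — the trade-off the
multi-objective formulation exists to expose.

A `cardiofit` console script wraps the same functionality
(`simulate`, `rm-profile`, `regions`, `fit`, `summarize`, `select`); run
configurations are YAML (`cardiofit fit --config run.yaml --out results/`).

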