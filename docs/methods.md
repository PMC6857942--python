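# Methods

## The fitting problem

Cardiac cell models are tuned almost exclusively against the action-potential
(AP) waveform. Two parameter sets can produce nearly identical APs while
differing sharply in membrane resistance R_m = ΔV_m/ΔI_m, the slope resistance
that governs how a cell loads its neighbours in tissue (source–sink coupling,
conduction velocity, susceptibility to early after-depolarizations). This
package fits both: the AP waveform and the voltage-resolved R_m profile, as a
1–3-objective minimization over 16 dimensionless scale factors on the maximal
conductances and transporter/uptake/release rates of the ten Tusscher et al.
(2004) human ventricular epicardial (TNNP) model:

* **f1 (mV)** — RMSE between reference and candidate AP on a shared uniform
  time grid, `sqrt(mean((V_ref(i·Ts) − V_fit(i·Ts))²))`.
* **f2 (GΩ)** — RMSE between the interpolated R_m-vs-voltage curves ("Rc")
  inside Allowed Region 2 (late repolarization), evaluated on the reference's
  dense voltage grid.
* **f3 (GΩ)** — absolute error of the scalar diastolic resistance R_d measured
  in Allowed Region 3.

Scenario 1 optimizes {f1} (single-objective GA mode), Scenario 2 {f1, f2},
Scenario 3 {f1, f2, f3}. The box bounds are the only constraints.

## R_m measurement

R_m at a voltage v on the AP is measured with a dual voltage-clamp protocol:
the beat is simulated until the first crossing of v within one of three
monotone AP segments (spike peak → notch, notch → dome, dome → end of beat;
segmentation avoids the ambiguity of a voltage occurring several times per
beat). From the state at the crossing, two clamp continuations hold V_m at
v + 10 and v − 10 mV for 5 ms; then

    R_m = 20 mV / (I_m+10 − I_m−10),

normalized to a 180 pF cell. With currents expressed as densities (pA/pF) the
normalization is a division by 180, and the normalized value is independent of
the cell's own capacitance — the invariant the passive-membrane oracle tests.

ΔI_m changes sign at specific voltages; there R_m diverges and refining the
measurement step only raises the recorded peak. Those singular voltages are
located by a 1 mV scan for sign changes of ΔI_m followed by bisection to
0.1 mV, and excluded by **disallowed regions**: closed intervals ±5 mV around
each singularity of *any* model in the fitting problem (base and reference),
merged when they overlap. The complementary **allowed regions** are labelled
from the depolarized end: 1 (plateau), 2 (late repolarization — this interval
contains the negative-R_m all-or-none-repolarization window, which is exactly
why it is fitted), 3 (diastolic). For the nominal TNNP model at 1 Hz the two
singularities sit near −2.6 and −62.4 mV, giving Allowed Region 2 ≈
(−57, −8) mV.

The Rc curve samples R_m every 5 mV inside Allowed Region 2 and connects the
nodes with a shape-preserving piecewise cubic (PCHIP) evaluated on a 0.5 mV
dense grid; PCHIP is exact on collinear nodes and cannot overshoot. R_d is
measured at the midpoint of Allowed Region 3 intersected with the beat's
diastolic voltage range (the bottom tenth of the AP amplitude). Candidates
reuse the reference's node grid, dense grid and R_d voltage so every
comparison is grid-consistent; regions are computed once per run and frozen.

## Simulation engine

The TNNP epicardial model (17 states) is implemented with its published
nominal constants; the 16 tunable quantities are premultiplied by the scale
factors. Integration uses the fixed-step operator-split scheme standard for
this model family — Rush–Larsen exponential updates for the 12 gates, forward
Euler for voltage and concentrations — at dt = 0.02 ms, compiled with numba.
Fixed stepping makes every trace bit-reproducible, keeps the cost of an
objective evaluation flat, and a test cross-checks one stimulated beat against
scipy's BDF stiff solver (rtol 1e-6): the waveforms agree to < 1 mV RMSE.
Voltage clamp is a reduced system (V_m substituted, dV_m/dt ≡ 0), so the hold
is exact. Pacing: 20 pA/pF, 2 ms pulses at 1 Hz; the 20th beat is analyzed
(T_s = 1 ms, G = 1000 samples). Crossing states are linearly interpolated
between recorded steps (0.2 ms apart), placing V_m within 10⁻³ mV of the
target.

Degenerate inputs: a waveform without notch/dome extrema (passive decay,
triangular AP) collapses to a single descending segment reported as part 3;
an empty singularity set yields a whole-span allowed partition by voltage
thirds with a warning; a singular Rc node is dropped with a warning (regions
should prevent it).

## Optimizer

NSGA-II is implemented from scratch: fast non-dominated sorting (checked
against a brute-force domination filter on random populations), crowding
distance with infinite boundary distances and a zero-span guard, binary
tournaments (rank, then crowding, then a fair coin), SBX crossover and
bounded polynomial mutation. Defaults follow the standard practice for this
algorithm: population 100, 10 000 evaluations, distribution indices
η_c = η_m = 20, crossover probability 0.9, mutation probability 1/16.
Scenario 1 uses the same engine with M = 1, where sorting degenerates to a
fitness ordering. Survivor selection fills fronts in order and truncates the
last admitted front by descending crowding (ties keep insertion order). The
reported set is the first front of the final combined parent+offspring
population. A single seeded generator drives every stochastic draw, so equal
seeds reproduce trials exactly.

Candidates whose evaluation fails — a non-finite state, or an AP that never
reaches the reference's measurement voltages (e.g. a non-repolarizing
parameter set) — receive a 10⁶ sentinel on every active objective, keeping
the evolutionary loop total.

From the final front a single preferred solution is chosen by normalizing
each objective to [0, 1] over the front, summing per solution, and taking the
argmin; the global normalizing denominator is constant across solutions and
cannot change the argmin (asserted as a property).

## Synthetic references and what they do (not) show

The original study fitted the TNNP model to five configurations of an
independent 67-state ventricular model. That reference model is out of scope
here; instead the five configurations are emulated by perturbed-TNNP
references with known ground truth: a fixed documented scale draw (baseline),
delayed-rectifier availability changes G_Kr = G_Ks × 2.5 / × 0.4 (shortened /
prolonged APD), and [K⁺]_o = 6.5 / 3.0 mM at nominal conductances
(hyper-/hypokalemia). Consequences:

* absolute error magnitudes are not comparable with the published table —
  a same-structure fit is easier than a cross-model fit;
* what *is* preserved, and what the tests check, is the framework's
  behaviour: region construction around singularities, grid-consistent
  objectives, Pareto trade-off direction (adding f2 worsens f1 and improves
  f2), recovery of identifiable parameters, and the published
  scenario-comparison percentages recomputed from the published averages;
* model-discrepancy effects (a reference outside the base model's manifold)
  are absent; on real data the Pareto front would not approach zero error.

The scaled-down experiment conditions used by the test suite and the
acceptance script are population 20 × 15 generations with 5 pacing beats —
enough beats for the slow gates to settle to within a few mV·ms of the
20-beat beat shape, and enough evaluations for the convergence and trade-off
properties to be stable across seeds.

The parameter-recovery experiment frees {G_Na, G_CaL, G_Kr, G_K1} and fixes
the remaining 12 scales at the truth. These four scale separate AP features
(upstroke, plateau, repolarization rate, resting potential) and are
individually identifiable from the AP alone; freeing a mutually compensating
pair such as G_Kr/G_Ks instead turns the criterion into a lottery over the
degenerate valley, which tests luck rather than optimizer correctness.

## Numerical choices

| quantity | value | note |
|---|---|---|
| integrator step dt | 0.02 ms | the model authors' step; halving changes APD by < 0.1 ms |
| recording stride | 0.2 ms | crossing interpolation error ≪ 10⁻³ mV |
| AP sample time T_s | 1 ms | G = 1000 per 1 Hz beat |
| clamp hold | 5 ms | per the measurement protocol |
| clamp displacement | ±10 mV | ΔV_m = 20 mV |
| singular ΔI_m threshold | 10⁻⁹ pA/pF | flags R_m = ∞ |
| singularity refinement | 0.1 mV | bisection on ΔI_m |
| region margin | 5 mV | around every singularity |
| Rc nodes / dense grid | 5 mV / 0.5 mV | PCHIP interpolation |
| R_d voltage | region-3 ∩ diastole midpoint | quantile 0.5, configurable |
| scale-factor bounds | [0.1, 3.0] | spans the configuration perturbations while keeping the model excitable; configurable |
| penalty sentinel | 10⁶ | per active objective |

## Known limitations

* The reference configurations are same-model perturbations; cross-model
  structural discrepancy is untested.
* Allowed/disallowed regions are frozen per run from the base-nominal and
  reference models; a candidate with singularities inside an allowed region
  is penalized only indirectly (singular nodes drop / unreachable voltages).
* The segmentation expects a spike–notch–dome epicardial morphology; other
  cell types degrade gracefully to the degenerate single-segment path but
  lose parts 1–2.
* Fixed-step integration trades step-size adaptivity for determinism and
  speed; stiffer parameterizations than the bounds allow would need a smaller
  dt.
* Serial evaluation only; the evolutionary loop is embarrassingly parallel
  but is kept single-threaded for reproducibility.
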