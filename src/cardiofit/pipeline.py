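"""Experiment grid: scenarios × reference configurations.

Wires the cell models, Rm analysis, objectives and the evolutionary
optimizer into seeded fitting trials:

* Scenario 1 — AP waveform only (single-objective GA mode),
* Scenario 2 — AP + Rc curve (bi-objective NSGA-II),
* Scenario 3 — AP + Rc + diastolic Rd (three objectives).

Each trial returns the preferred solution of the final Pareto front with
its inactive objectives filled in a posteriori, and trials aggregate into
a summary table of mean ± SD per (scenario, configuration) cell.

The reference "experimental data" are perturbed-TNNP configurations with
known ground-truth scale factors; allowed/disallowed voltage regions are
computed once per (base, reference) pair from the union of both models'
singularities and frozen for the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .models import (DEFAULT_LB, DEFAULT_UB, PARAM_NAMES, ModelParameters,
                     build_tnnp_model, configuration_spec,
                     make_reference_configuration)
from .moea import Individual, NSGAConfig, nsga2, select_preferred
from .objectives import ObjectiveVector, ReferenceBundle, evaluate_candidate
from .pacing import StimulusProtocol, pace_to_steady_state
from .rm import build_rc_curve, define_regions, find_singularities, measure_rd

CONFIGURATION_NAMES = ("baseline", "shortened_apd", "prolonged_apd",
                       "hyperkalemia", "hypokalemia")


@dataclass
class ScenarioSpec:
    """Which objectives are active: 1 → {f1}, 2 → {f1,f2}, 3 → {f1,f2,f3}."""

    id: int

    def __post_init__(self):
        if self.id not in (1, 2, 3):
            raise ConfigurationError(f"scenario id must be 1, 2 or 3, got {self.id}")

    @property
    def M(self) -> int:
        return self.id

    @property
    def active_objectives(self) -> frozenset:
        return frozenset(range(1, self.id + 1))


@dataclass
class TrialResult:
    """One seeded fitting trial: the Eq-style selected solution and its front."""

    scenario: int
    configuration: str
    seed: int
    selected_x: np.ndarray
    selected_index: int
    f1_rmse_ap_mV: float
    f2_rmse_rc_GOhm: float
    f3_ae_rd_GOhm: float
    front: list[Individual] = field(repr=False, default_factory=list)
    history: list[np.ndarray] = field(repr=False, default_factory=list)


@dataclass
class SummaryTable:
    """Ave/Std of the three metrics per (scenario, configuration) cell."""

    table: pd.DataFrame

    COLUMNS = ("rmse_ap_ave_mV", "rmse_ap_std_mV", "rmse_rc_ave_GOhm",
               "rmse_rc_std_GOhm", "ae_rd_ave_GOhm", "ae_rd_std_GOhm",
               "n_trials")


_BUNDLE_CACHE: dict[tuple, ReferenceBundle] = {}


def prepare_reference(configuration: str, protocol: StimulusProtocol,
                      margin_mV: float = 5.0, scan_step_mV: float = 1.0,
                      node_spacing_mV: float = 5.0,
                      dense_spacing_mV: float = 0.5,
                      use_cache: bool = True) -> ReferenceBundle:
    """Simulate a reference configuration and freeze its fitting targets.

    The allowed/disallowed regions are built from the union of the
    singularities of the nominal base model and of the reference model, so
    a voltage is disallowed if it is singular in *any* model of interest.
    """
    key = (configuration, protocol.amplitude_pA_per_pF, protocol.duration_ms,
           protocol.cycle_length_ms, protocol.n_beats, margin_mV,
           scan_step_mV, node_spacing_mV, dense_spacing_mV)
    if use_cache and key in _BUNDLE_CACHE:
        return _BUNDLE_CACHE[key]

    spec = configuration_spec(configuration)
    reference = make_reference_configuration(spec)
    base = build_tnnp_model(conditions={"ko_mM": spec.ko_mM})

    ref_paced = pace_to_steady_state(reference, protocol)
    base_paced = pace_to_steady_state(base, protocol)
    if ref_paced.trace.vm.max() < 0.0:
        raise ConfigurationError(
            f"reference configuration {configuration!r} fails to produce an AP")

    ref_sing = find_singularities(reference, protocol, scan_step_mV,
                                  paced=ref_paced)
    base_sing = find_singularities(base, protocol, scan_step_mV,
                                   paced=base_paced)
    span = (min(ref_paced.trace.vm.min(), base_paced.trace.vm.min()),
            max(ref_paced.trace.vm.max(), base_paced.trace.vm.max()))
    regions = define_regions([base_sing, ref_sing], margin_mV, span_mV=span)

    rc = build_rc_curve(reference, protocol, regions,
                        node_spacing_mV=node_spacing_mV,
                        dense_spacing_mV=dense_spacing_mV, paced=ref_paced)
    rd = measure_rd(reference, ref_paced.beat_start_state, protocol, regions,
                    paced=ref_paced)
    bundle = ReferenceBundle(trace=ref_paced.trace, rc_curve=rc, rd=rd,
                             regions=regions, protocol=protocol,
                             ko_mM=spec.ko_mM, configuration=configuration,
                             reference_scales=dict(reference.params.scale))
    if use_cache:
        _BUNDLE_CACHE[key] = bundle
    return bundle


def make_evaluator(bundle: ReferenceBundle, M: int,
                   free_names: tuple[str, ...] | None = None,
                   fixed_scales: dict[str, float] | None = None):
    """Build a total evaluator mapping a parameter vector to objectives.

    With ``free_names`` only that subset of scale factors is optimized;
    the rest are fixed at ``fixed_scales`` (useful for identifiability and
    recovery experiments).  Returns ``(evaluator, lb, ub)``.
    """
    if free_names is None:
        free_names = PARAM_NAMES
    fixed = {name: 1.0 for name in PARAM_NAMES}
    if fixed_scales:
        fixed.update(fixed_scales)

    def evaluator(x: np.ndarray) -> ObjectiveVector:
        scales = dict(fixed)
        for name, v in zip(free_names, x):
            scales[name] = float(v)
        params = ModelParameters(scale=scales)
        return evaluate_candidate(params, bundle, scenario_M=M)

    n = len(free_names)
    return evaluator, np.full(n, DEFAULT_LB), np.full(n, DEFAULT_UB)


def run_trial(scenario: int | ScenarioSpec, configuration: str, seed: int,
              optimizer_config: NSGAConfig | None = None,
              protocol: StimulusProtocol | None = None,
              bundle: ReferenceBundle | None = None,
              callback=None) -> TrialResult:
    """Run one seeded optimization trial for a scenario/configuration cell.

    The preferred solution of the final first front is selected by the
    normalized-sum rule; objectives not active in the scenario are then
    computed a posteriori for that solution.
    """
    scenario = scenario if isinstance(scenario, ScenarioSpec) \
        else ScenarioSpec(scenario)
    protocol = protocol or StimulusProtocol()
    if bundle is None:
        bundle = prepare_reference(configuration, protocol)
    evaluator, lb, ub = make_evaluator(bundle, scenario.M)

    cfg = optimizer_config or NSGAConfig()
    cfg = NSGAConfig(pop_size=cfg.pop_size, max_evaluations=cfg.max_evaluations,
                     eta_crossover=cfg.eta_crossover,
                     eta_mutation=cfg.eta_mutation,
                     crossover_prob=cfg.crossover_prob,
                     mutation_prob=cfg.mutation_prob, seed=seed, lb=lb, ub=ub)
    front, history = nsga2(evaluator, cfg, callback=callback)

    F = np.array([ind.objectives for ind in front])
    idx = select_preferred(F)
    selected = front[idx]

    full = evaluate_candidate(
        ModelParameters.from_vector(selected.x), bundle, scenario_M=3)
    return TrialResult(
        scenario=scenario.id, configuration=configuration, seed=seed,
        selected_x=selected.x.copy(), selected_index=idx,
        f1_rmse_ap_mV=float(full.f1_rmse_ap_mV),
        f2_rmse_rc_GOhm=float(full.f2_rmse_rc_GOhm),
        f3_ae_rd_GOhm=float(full.f3_ae_rd_GOhm),
        front=front, history=history)


def summarize(trials: list[TrialResult]) -> SummaryTable:
    """Sample mean and SD (n-1 denominator) of each metric per cell."""
    if not trials:
        raise ConfigurationError("no trials to summarize")
    rows = {}
    groups: dict[tuple[int, str], list[TrialResult]] = {}
    for tr in trials:
        groups.setdefault((tr.scenario, tr.configuration), []).append(tr)
    for (scen, conf), cell in sorted(groups.items()):
        metrics = np.array([[t.f1_rmse_ap_mV, t.f2_rmse_rc_GOhm,
                             t.f3_ae_rd_GOhm] for t in cell])
        ave = metrics.mean(axis=0)
        std = metrics.std(axis=0, ddof=1) if len(cell) > 1 else np.zeros(3)
        rows[(scen, conf)] = [ave[0], std[0], ave[1], std[1], ave[2], std[2],
                              len(cell)]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(SummaryTable.COLUMNS))
    df.index = pd.MultiIndex.from_tuples(df.index,
                                         names=["scenario", "configuration"])
    df["n_trials"] = df["n_trials"].astype(int)
    return SummaryTable(table=df)


def heatmap_data(front_objectives: np.ndarray) -> np.ndarray:
    """Front matrix ordered by ascending f1 with min-max-normalized columns.

    Rows are solutions sorted by the first objective; each column is
    rescaled to [0, 1] (a constant objective yields a zero column), which
    visualizes the conflict between objectives.
    """
    F = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    F = F[np.argsort(F[:, 0], kind="stable")]
    out = np.zeros_like(F)
    for m in range(F.shape[1]):
        span = F[:, m].max() - F[:, m].min()
        if span > 0:
            out[:, m] = (F[:, m] - F[:, m].min()) / span
    return out
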