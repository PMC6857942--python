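"""Fitness functions for the fitting problem.

Three objectives, all minimized:

* ``f1`` — RMSE between reference and candidate AP waveforms (mV),
* ``f2`` — RMSE between the interpolated Rm curves in Allowed Region 2 (GΩ),
* ``f3`` — absolute error of the diastolic resistance Rd (GΩ),

plus the relative-change metric ``|E1 - E2| / E1 × 100`` used to compare
scenario outcomes.

Candidates whose simulation fails (non-finite state, or an AP that never
reaches the reference's measurement voltages) receive a large penalty
sentinel on every active objective so the evolutionary loop stays total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (CardiofitError, ConfigurationError, ContractError,
                         NotReachableError, SimulationError)
from .models import CellModel, ModelParameters, build_tnnp_model
from .pacing import APTrace, StimulusProtocol, pace_to_steady_state
from .rm import RcCurve, RdValue, VoltageRegions, build_rc_curve, measure_rd

#: objective value assigned to candidates whose evaluation fails
PENALTY_SENTINEL = 1e6


@dataclass
class ObjectiveVector:
    """Values of the (up to three) objectives with their active mask."""

    f1_rmse_ap_mV: float | None = None
    f2_rmse_rc_GOhm: float | None = None
    f3_ae_rd_GOhm: float | None = None
    active_mask: tuple[bool, bool, bool] = (True, True, True)
    penalized: bool = False

    def __post_init__(self):
        if not any(self.active_mask):
            raise ValueError("at least one objective must be active")
        for active, v in zip(self.active_mask, self._all()):
            if active and (v is None or not np.isfinite(v) or v < 0):
                raise ValueError(f"active objective has invalid value {v}")

    def _all(self):
        return (self.f1_rmse_ap_mV, self.f2_rmse_rc_GOhm, self.f3_ae_rd_GOhm)

    @property
    def M(self) -> int:
        return sum(self.active_mask)

    def active_values(self) -> np.ndarray:
        return np.array([v for a, v in zip(self.active_mask, self._all()) if a])


@dataclass
class ReferenceBundle:
    """Everything needed to evaluate candidates against one reference.

    Computed once per optimization run: the reference AP trace, its Rc
    curve (whose node and dense grids the candidates reuse), the diastolic
    Rd (whose measurement voltage the candidates reuse), the frozen
    allowed/disallowed regions and the simulation conditions.
    """

    trace: APTrace
    rc_curve: RcCurve
    rd: RdValue
    regions: VoltageRegions
    protocol: StimulusProtocol
    ko_mM: float
    configuration: str = ""
    reference_scales: dict | None = None


def rmse_ap(reference: APTrace, candidate: APTrace) -> float:
    """Root-mean-squared error between two APs on a shared time grid (mV)."""
    if reference.G != candidate.G or abs(reference.ts_ms - candidate.ts_ms) > 1e-12:
        raise ContractError("AP traces must share the same T_s and G")
    return float(np.sqrt(np.mean((reference.vm - candidate.vm) ** 2)))


def rmse_rc(reference: RcCurve, candidate: RcCurve) -> float:
    """RMSE between two Rc curves on the reference's dense grid (GΩ)."""
    if reference.D != candidate.D or not np.allclose(
            reference.dense_voltages_mV, candidate.dense_voltages_mV,
            atol=1e-9, rtol=0.0):
        raise ContractError("Rc curves must share the same dense abscissae")
    return float(np.sqrt(np.mean(
        (reference.dense_rm_GOhm - candidate.dense_rm_GOhm) ** 2)))


def ae_rd(reference: RdValue, candidate: RdValue) -> float:
    """Absolute error of the diastolic resistance (GΩ)."""
    return float(abs(reference.rd_GOhm - candidate.rd_GOhm))


def relative_change(e1: float, e2: float) -> float:
    """Relative percentage of improvement or deterioration, |E1-E2|/E1 × 100."""
    if e1 == 0:
        raise ValueError("relative change is undefined for E1 = 0")
    return abs(e1 - e2) / e1 * 100.0


def _mask_for(M: int) -> tuple[bool, bool, bool]:
    if M not in (1, 2, 3):
        raise ConfigurationError(f"number of objectives must be 1, 2 or 3, got {M}")
    return (True, M >= 2, M >= 3)


def evaluate_candidate(params: ModelParameters, reference: ReferenceBundle,
                       regions: VoltageRegions | None = None,
                       scenario_M: int = 3,
                       model: CellModel | None = None) -> ObjectiveVector:
    """Evaluate the active objectives of one candidate parameter vector.

    The candidate base model is paced to steady state under the reference's
    protocol and extracellular potassium; its Rc curve and Rd are measured
    on the reference's grids so that the objective comparisons are
    well-defined.  A failed simulation yields the penalty sentinel on every
    active objective rather than an exception.
    """
    mask = _mask_for(scenario_M)
    regions = regions if regions is not None else reference.regions
    try:
        if model is None:
            model = build_tnnp_model(params, {"ko_mM": reference.ko_mM})
        paced = pace_to_steady_state(model, reference.protocol,
                                     ts_ms=reference.trace.ts_ms)
        f1 = rmse_ap(reference.trace, paced.trace)
        f2 = f3 = None
        if scenario_M >= 2:
            cand_rc = build_rc_curve(
                model, reference.protocol, regions, paced=paced,
                node_voltages=reference.rc_curve.node_voltages_mV,
                dense_voltages=reference.rc_curve.dense_voltages_mV)
            f2 = rmse_rc(reference.rc_curve, cand_rc)
        if scenario_M >= 3:
            cand_rd = measure_rd(model, paced.beat_start_state,
                                 reference.protocol, regions, paced=paced,
                                 at_voltage=reference.rd.v_mV)
            if not np.isfinite(cand_rd.rd_GOhm):
                raise NotReachableError("singular candidate Rd")
            f3 = ae_rd(reference.rd, cand_rd)
        return ObjectiveVector(f1, f2, f3, active_mask=mask)
    except (SimulationError, NotReachableError, ConfigurationError,
            ContractError, CardiofitError):
        s = PENALTY_SENTINEL
        return ObjectiveVector(
            s if mask[0] else None, s if mask[1] else None,
            s if mask[2] else None, active_mask=mask, penalized=True)
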