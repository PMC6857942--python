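"""CSV/JSON writers, readers and deterministic test fixtures.

All interchange is plain text: traces, Rm profiles and Pareto fronts as
CSV (pandas), voltage regions as JSON.  Numbers are serialized with six
decimal places so written tables round-trip at documented precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .models import (CellModel, build_passive_membrane, build_static_membrane,
                     make_reference_configuration)
from .pacing import APTrace
from .pipeline import SummaryTable, TrialResult
from .rm import RcCurve, RmProfile, VoltageRegions

FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_trace(trace: APTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.t, "vm_mV": trace.vm}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_trace(path: str | Path) -> APTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    ts = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return APTrace(t=t, vm=df["vm_mV"].to_numpy(), ts_ms=round(ts, 9))


def write_states(t: np.ndarray, states: np.ndarray, names: list[str],
                 path: str | Path) -> None:
    """Full state-trajectory export (columns: time_ms, then state names)."""
    df = pd.DataFrame(states, columns=names)
    df.insert(0, "time_ms", t)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_rm_profile(profile: RmProfile, path: str | Path) -> None:
    pd.DataFrame({
        "v_mV": [p.v_mV for p in profile.points],
        "rm_GOhm": [p.rm_GOhm for p in profile.points],
        "part": [p.part for p in profile.points],
        "singular": [p.singular for p in profile.points],
    }).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_rc_curve(curve: RcCurve, path: str | Path) -> None:
    pd.DataFrame({"v_mV": curve.dense_voltages_mV,
                  "rc_GOhm": curve.dense_rm_GOhm}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def regions_to_json(regions: VoltageRegions, path: str | Path | None = None) -> str:
    doc = json.dumps({
        "singularities": regions.singular_voltages_mV,
        "disallowed": [list(iv) for iv in regions.disallowed],
        "allowed": [list(iv) for iv in regions.allowed],
    }, indent=2)
    if path is not None:
        Path(path).write_text(doc)
    return doc


def regions_from_json(doc: str | Path) -> VoltageRegions:
    if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc
                                 and Path(doc).exists()):
        doc = Path(doc).read_text()
    data = json.loads(doc)
    return VoltageRegions(
        singular_voltages_mV=data["singularities"],
        disallowed=[tuple(iv) for iv in data["disallowed"]],
        allowed=[tuple(iv) for iv in data["allowed"]])


def write_front(front, path: str | Path) -> None:
    """Pareto front export: solution id, scales, objectives, rank, crowding."""
    from .models import PARAM_NAMES
    rows = []
    for i, ind in enumerate(front):
        row = {"solution": i}
        n = len(ind.x)
        names = PARAM_NAMES if n == len(PARAM_NAMES) else \
            [f"x{k}" for k in range(n)]
        row.update({name: v for name, v in zip(names, ind.x)})
        row.update({f"f{m + 1}": v for m, v in enumerate(ind.objectives)})
        row.update({"rank": ind.rank, "crowding": ind.crowding})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trials(trials: list[TrialResult], path: str | Path) -> None:
    from .models import PARAM_NAMES
    rows = []
    for tr in trials:
        row = {"scenario": tr.scenario, "configuration": tr.configuration,
               "seed": tr.seed, "rmse_ap_mV": tr.f1_rmse_ap_mV,
               "rmse_rc_GOhm": tr.f2_rmse_rc_GOhm,
               "ae_rd_GOhm": tr.f3_ae_rd_GOhm}
        row.update({name: v for name, v in zip(PARAM_NAMES, tr.selected_x)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_history(history, path: str | Path) -> None:
    """Per-generation best objective values of one optimizer run."""
    H = np.atleast_2d(np.asarray(history, dtype=float))
    df = pd.DataFrame(H, columns=[f"best_f{m + 1}" for m in range(H.shape[1])])
    df.insert(0, "generation", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(summary: SummaryTable, path: str | Path) -> None:
    """Summary-table CSV (columns ordered RMSE_AP, RMSE_Rc, AE_Rd)."""
    if summary.table.empty:
        raise ConfigurationError("cannot write an empty summary table")
    summary.table.to_csv(path, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> SummaryTable:
    df = pd.read_csv(path, index_col=[0, 1])
    df["n_trials"] = df["n_trials"].astype(int)
    return SummaryTable(table=df)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: documented cubic-membrane constants: I(V) = a (V-E1)(V-E2)(V-E3).
#: ΔIm(v) = I(v+10) - I(v-10) = 20 a (3v² + 320v + 400), whose only root in
#: the physiological span is v0 below.
CUBIC_A = 1e-4
CUBIC_ROOTS = (-150.0, -40.0, 30.0)
CUBIC_SINGULARITY_MV = (-320.0 + math.sqrt(320.0 ** 2 - 4 * 3 * 400.0)) / 6.0


@dataclass
class Fixture:
    kind: str
    obj: object
    ground_truth: dict


def _spike_notch_dome_trace() -> tuple[APTrace, dict]:
    """Synthetic AP-like waveform with analytically known extrema.

    Built from half-cosine arcs between control points (rest −85 mV,
    peak +35 at 10 ms, notch +10 at 30 ms, dome +22 at 80 ms, rest from
    400 ms), so each piece is smooth and strictly monotone.
    """
    knots = [(0.0, -85.0), (10.0, 35.0), (30.0, 10.0), (80.0, 22.0),
             (400.0, -85.0)]
    t = np.arange(1000.0)
    vm = np.full_like(t, -85.0)
    for (t0, v0), (t1, v1) in zip(knots[:-1], knots[1:]):
        seg = (t >= t0) & (t <= t1)
        phase = (t[seg] - t0) / (t1 - t0)
        vm[seg] = v0 + (v1 - v0) * (1 - np.cos(np.pi * phase)) / 2
    trace = APTrace(t=t, vm=vm, ts_ms=1.0)
    truth = {"peak": (10.0, 35.0), "notch": (30.0, 10.0), "dome": (80.0, 22.0)}
    return trace, truth


def make_fixture(kind: str) -> Fixture:
    """Deterministic fixtures with documented ground truth."""
    if kind == "passive":
        model = build_passive_membrane(1.0, -85.0, 180.0)
        return Fixture(kind, model, {"resistance_GOhm": 1.0,
                                     "reversal_mV": -85.0})
    if kind == "cubic_static":
        e1, e2, e3 = CUBIC_ROOTS

        def current(v, a=CUBIC_A):
            return a * (v - e1) * (v - e2) * (v - e3)

        model = build_static_membrane(current, name="cubic_static",
                                      initial_mV=-85.0)
        return Fixture(kind, model, {"singularity_mV": CUBIC_SINGULARITY_MV,
                                     "roots": CUBIC_ROOTS, "a": CUBIC_A})
    if kind == "spike_notch_dome_trace":
        trace, truth = _spike_notch_dome_trace()
        return Fixture(kind, trace, truth)
    if kind == "perturbed_tnnp_reference":
        model: CellModel = make_reference_configuration("baseline")
        return Fixture(kind, model,
                       {"scales": dict(model.params.scale)})
    raise ConfigurationError(f"unknown fixture kind: {kind!r}")
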