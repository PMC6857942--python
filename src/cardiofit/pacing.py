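"""Stimulated pacing, steady-state beats, and voltage-clamp continuations.

The engine advances a :class:`~cardiofit.models.CellModel` with a fixed-step
operator-split integrator (Rush–Larsen gates + forward Euler for voltage and
concentrations for the compiled TNNP kernel; forward Euler for the simple
generic membranes).  Fixed stepping makes every trace bit-reproducible and
keeps the per-evaluation cost of the optimization loop predictable.

Voltage clamp is implemented as a reduced system: the stored Vm is replaced
by the hold voltage and dVm/dt is zeroed, so the hold is exact and carries
no stiffness penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tnnp_kernel as _kernel
from .exceptions import NotReachableError, SimulationError
from .models import CellModel

#: integrator step (ms); the value the TNNP authors used for this model
DEFAULT_DT_MS = 0.02
#: spacing of recorded states on the analysis beat (ms)
DEFAULT_RECORD_DT_MS = 0.2


@dataclass
class StimulusProtocol:
    """Current-pulse pacing protocol (defaults: 20 pA/pF, 2 ms, 1 Hz, 20 beats)."""

    amplitude_pA_per_pF: float = 20.0
    duration_ms: float = 2.0
    cycle_length_ms: float = 1000.0
    n_beats: int = 20

    def __post_init__(self):
        if min(self.amplitude_pA_per_pF, self.duration_ms,
               self.cycle_length_ms, self.n_beats) <= 0:
            raise ValueError("all stimulus protocol fields must be positive")


@dataclass
class APTrace:
    """Uniformly sampled Vm time series for one paced beat."""

    t: np.ndarray
    vm: np.ndarray
    ts_ms: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.t.shape != self.vm.shape:
            raise ValueError("t and vm must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - self.ts_ms)) > 1e-9:
                raise ValueError("trace samples must be uniformly spaced at ts_ms")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.vm))):
            raise ValueError("trace contains non-finite values")

    @property
    def G(self) -> int:
        return len(self.t)


@dataclass
class ClampResult:
    """Membrane current recorded at the end of a voltage-clamp hold."""

    hold_voltage_mV: float
    im_end_pA_per_pF: float
    hold_duration_ms: float


@dataclass
class BeatRecording:
    """Dense record of one beat: states every ``record_dt`` ms from stimulus onset."""

    t: np.ndarray
    states: np.ndarray  # (n, state_dimension)
    model: CellModel
    protocol: StimulusProtocol

    @property
    def vm(self) -> np.ndarray:
        return self.states[:, self.model.vm_index]

    def state_at(self, time_ms: float) -> np.ndarray:
        """Full state at an arbitrary time by linear interpolation."""
        t = self.t
        if not (t[0] - 1e-9 <= time_ms <= t[-1] + 1e-9):
            raise ValueError(f"time {time_ms} outside recording [{t[0]}, {t[-1]}]")
        i = min(np.searchsorted(t, time_ms, side="right"), len(t) - 1)
        a, b = i - 1, i
        if a < 0:
            return self.states[0].copy()
        w = (time_ms - t[a]) / (t[b] - t[a])
        return (1 - w) * self.states[a] + w * self.states[b]

    def trace(self, ts_ms: float = 1.0) -> APTrace:
        """Resample Vm onto the uniform analysis grid (default T_s = 1 ms)."""
        n = int(round(self.protocol.cycle_length_ms / ts_ms))
        tt = np.arange(n) * ts_ms
        vm = np.interp(tt, self.t, self.vm)
        return APTrace(t=tt, vm=vm, ts_ms=ts_ms)


@dataclass
class PacedBeat:
    """Result of pacing to steady state: the final beat and its onset state."""

    beat_start_state: np.ndarray
    trace: APTrace
    recording: BeatRecording

    def __iter__(self):  # allow (state, trace) unpacking
        return iter((self.beat_start_state, self.trace))


def _integrate(model: CellModel, y0: np.ndarray, duration_ms: float,
               dt: float, stim_amp: float, stim_ms: float,
               clamp_v: float, clamped: bool, stride: int):
    """Advance ``duration_ms`` and return (times, states) at ``stride`` steps."""
    n_steps = int(round(duration_ms / dt))
    if model.kind == "tnnp":
        stim_steps = int(round(stim_ms / dt))
        rec, status, fail_step = _kernel.integrate(
            np.asarray(y0, dtype=float), model.p, dt, n_steps, stim_amp,
            stim_steps, clamp_v, clamped, stride)
        if status != 0:
            raise SimulationError(
                f"non-finite state in model {model.name}", time_ms=fail_step * dt)
        t = np.arange(rec.shape[0]) * (stride * dt)
        return t, rec
    # generic fixed-step forward-Euler path for simple membranes
    y = np.array(y0, dtype=float)
    vm = model.vm_index
    if clamped:
        y[vm] = clamp_v
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, len(y)))
    out[0] = y
    k = 1
    for i in range(n_steps):
        t = i * dt
        dy = model.rhs(t, y)
        if clamped:
            dy[vm] = 0.0
        elif t < stim_ms:
            dy[vm] += stim_amp  # depolarizing stimulus
        y = y + dt * dy
        if clamped:
            y[vm] = clamp_v
        if (i + 1) % stride == 0:
            out[k] = y
            k += 1
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state in model {model.name}",
                              time_ms=n_steps * dt)
    t = np.arange(k) * (stride * dt)
    return t, out[:k]


def simulate_beat(model: CellModel, state: np.ndarray,
                  protocol: StimulusProtocol, dt: float = DEFAULT_DT_MS,
                  record_dt: float = DEFAULT_RECORD_DT_MS) -> BeatRecording:
    """Run one stimulated cycle from ``state``, recording the trajectory."""
    stride = max(int(round(record_dt / dt)), 1)
    t, rec = _integrate(model, state, protocol.cycle_length_ms, dt,
                        protocol.amplitude_pA_per_pF, protocol.duration_ms,
                        0.0, False, stride)
    return BeatRecording(t=t, states=rec, model=model, protocol=protocol)


def pace_to_steady_state(model: CellModel, protocol: StimulusProtocol,
                         dt: float = DEFAULT_DT_MS, ts_ms: float = 1.0,
                         record_dt: float = DEFAULT_RECORD_DT_MS) -> PacedBeat:
    """Pace ``n_beats`` cycles and return the final (analysis) beat.

    Beats 1..n-1 are integrated without recording; the final beat is
    recorded densely and resampled onto the uniform ``ts_ms`` grid.
    """
    state = model.initial_state.copy()
    n_pre = protocol.n_beats - 1
    for b in range(n_pre):
        n_steps = int(round(protocol.cycle_length_ms / dt))
        try:
            _, rec = _integrate(model, state, protocol.cycle_length_ms, dt,
                                protocol.amplitude_pA_per_pF,
                                protocol.duration_ms, 0.0, False, n_steps)
        except SimulationError as err:
            raise SimulationError(
                str(err), time_ms=b * protocol.cycle_length_ms +
                (err.time_ms or 0.0)) from err
        state = rec[-1]
    recording = simulate_beat(model, state, protocol, dt=dt, record_dt=record_dt)
    return PacedBeat(beat_start_state=np.array(state), trace=recording.trace(ts_ms),
                     recording=recording)


def run_to_voltage(model: CellModel, beat_state: np.ndarray,
                   protocol: StimulusProtocol, target_mV: float,
                   segment: int, recording: BeatRecording | None = None,
                   segments=None) -> np.ndarray:
    """State at the first crossing of ``target_mV`` within an AP segment.

    The crossing is located on the recorded trajectory of the beat started
    from ``beat_state`` and refined by linear interpolation between
    recorded states (the returned Vm equals the target to < 1e-3 mV).
    For one-state (static/passive) membranes the state at a voltage *is*
    that voltage, so it is returned directly when in range.
    """
    if recording is None:
        recording = simulate_beat(model, beat_state, protocol)
    if segments is None:
        from .rm import segment_ap  # deferred to avoid an import cycle
        segments = segment_ap(recording.trace(1.0))

    t0, t1 = segments.time_window(segment)
    mask = (recording.t >= t0 - 1e-9) & (recording.t <= t1 + 1e-9)
    idx = np.nonzero(mask)[0]
    if len(idx) < 2:
        raise NotReachableError(
            f"segment {segment} spans fewer than two recorded samples")
    tseg = recording.t[idx]
    vseg = recording.vm[idx]

    if model.state_dimension == 1:
        lo, hi = min(vseg[0], vseg[-1]), max(vseg[0], vseg[-1])
        if not (lo - 1e-9 <= target_mV <= hi + 1e-9):
            raise NotReachableError(
                f"{target_mV} mV not attained in segment {segment}")
        return np.array([target_mV])

    resid = vseg - target_mV
    # exact hit (e.g. target equal to a boundary extremum)
    hits = np.nonzero(np.abs(resid) <= 1e-3)[0]
    if len(hits):
        state = recording.states[idx[hits[0]]].copy()
        state[model.vm_index] = target_mV
        return state
    sign_change = np.nonzero(resid[:-1] * resid[1:] < 0)[0]
    if not len(sign_change):
        raise NotReachableError(
            f"{target_mV} mV not attained in segment {segment}")
    a = idx[sign_change[0]]
    b = a + 1
    va, vb = recording.vm[a], recording.vm[b]
    w = (target_mV - va) / (vb - va)
    state = (1 - w) * recording.states[a] + w * recording.states[b]
    state[model.vm_index] = target_mV
    return state


def voltage_clamp(model: CellModel, start_state: np.ndarray, hold_mV: float,
                  hold_ms: float = 5.0, dt: float = DEFAULT_DT_MS) -> ClampResult:
    """Hold Vm at ``hold_mV`` for ``hold_ms`` and record I_m at the end.

    All non-voltage state variables evolve under the model equations with
    Vm fixed; the recorded current is the total ionic current at the held
    voltage after the gating variables have relaxed for ``hold_ms``.
    """
    start_state = np.asarray(start_state, dtype=float)
    if not np.all(np.isfinite(start_state)):
        raise SimulationError("clamp start state is non-finite", time_ms=0.0)
    n_steps = max(int(round(hold_ms / dt)), 1)
    _, rec = _integrate(model, start_state, n_steps * dt, dt, 0.0, 0.0,
                        hold_mV, True, n_steps)
    y_end = rec[-1]
    return ClampResult(hold_voltage_mV=hold_mV,
                       im_end_pA_per_pF=float(model.total_ionic_current(y_end)),
                       hold_duration_ms=hold_ms)


def apd90(trace: APTrace) -> float:
    """Action-potential duration at 90 % repolarization (ms).

    Measured from the maximum-upstroke sample to the first subsequent
    return below V_peak - 0.9 * (V_peak - V_rest), with V_rest taken as the
    pre-stimulus minimum of the trace.
    """
    vm = trace.vm
    i_peak = int(np.argmax(vm))
    v_peak = vm[i_peak]
    v_rest = float(np.min(vm))
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.nonzero(vm[i_peak:] <= v90)[0]
    if not len(below):
        return float(trace.t[-1] - trace.t[i_peak])
    i_cross = i_peak + below[0]
    # linear interpolation between the bracketing samples
    if i_cross > i_peak:
        va, vb = vm[i_cross - 1], vm[i_cross]
        frac = (va - v90) / (va - vb) if va != vb else 0.0
        t_cross = trace.t[i_cross - 1] + frac * trace.ts_ms
    else:
        t_cross = trace.t[i_cross]
    return float(t_cross - trace.t[i_peak])
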