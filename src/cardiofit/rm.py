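"""Voltage-resolved membrane-resistance (Rm) analysis.

Rm at a point on the action potential is measured with a dual voltage-clamp
protocol: the beat is simulated to the voltage of interest, then continued
twice in voltage-clamp mode at 10 mV above and 10 mV below that voltage;
after 5 ms of clamp the membrane currents I_m+10 and I_m-10 are recorded and

    Rm = ΔVm / ΔIm = 20 mV / (I_m+10 - I_m-10),

normalized to a cell capacitance of 180 pF (currents are densities in
pA/pF, so Rm[GΩ] = (ΔVm/ΔIm) / 180).

Because the same voltage can occur several times during a beat, the AP is
segmented into three parts at its post-upstroke extrema (spike peak, notch,
dome) and each part is treated as a separate monotone voltage axis.

ΔIm changes sign at specific voltages where Rm diverges (the borders of the
all-or-none-repolarization window); those singular voltages are excluded
from fitting by construction of allowed/disallowed voltage regions with a
5 mV safety margin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, medfilt

from .exceptions import ConfigurationError, NotReachableError
from .models import NORMALIZATION_CAPACITANCE_PF, CellModel
from .pacing import (APTrace, BeatRecording, PacedBeat, StimulusProtocol,
                     pace_to_steady_state, run_to_voltage, voltage_clamp)

#: clamp displacement from the point of interest (mV); ΔVm is twice this
CLAMP_STEP_MV = 10.0
#: ΔIm magnitudes below this are flagged singular (pA/pF)
SINGULAR_DELTA_IM = 1e-9
#: bisection tolerance for singular-voltage refinement (mV)
SINGULARITY_TOL_MV = 0.1
#: default margin of disallowed regions around singularities (mV)
REGION_MARGIN_MV = 5.0


@dataclass
class APSegments:
    """Three-part segmentation of one beat at its post-upstroke extrema.

    ``boundaries`` are (time, voltage) pairs: spike peak, notch (local
    minimum) and dome (local maximum).  Part 1 = peak→notch, part 2 =
    notch→dome, part 3 = dome→end of beat; within each part the smoothed
    voltage is monotone, so each voltage maps to at most one time per part.
    """

    boundaries: list[tuple[float, float]]
    t_end: float
    degenerate: bool = False

    def time_window(self, part: int) -> tuple[float, float]:
        if self.degenerate:
            if part == 3:
                return self.boundaries[0][0], self.t_end
            raise NotReachableError(
                f"degenerate segmentation has no part {part}")
        if part not in (1, 2, 3):
            raise ValueError(f"part must be 1, 2 or 3, got {part}")
        t_peak, t_notch, t_dome = (b[0] for b in self.boundaries)
        return {1: (t_peak, t_notch), 2: (t_notch, t_dome),
                3: (t_dome, self.t_end)}[part]

    def part_index(self, time_ms: float) -> int:
        if self.degenerate:
            return 3
        for part in (1, 2, 3):
            t0, t1 = self.time_window(part)
            if t0 - 1e-9 <= time_ms <= t1 + 1e-9:
                return part
        raise ValueError(f"time {time_ms} precedes the AP peak")

    def parts(self) -> tuple[int, ...]:
        return (3,) if self.degenerate else (1, 2, 3)


@dataclass
class RmPoint:
    """One membrane-resistance measurement (normalized to 180 pF)."""

    v_mV: float
    rm_GOhm: float
    part: int
    delta_im: float

    @property
    def singular(self) -> bool:
        return not math.isfinite(self.rm_GOhm)


@dataclass
class RmProfile:
    """Ordered collection of RmPoints for one model."""

    points: list[RmPoint]
    model_id: str = ""

    def __post_init__(self):
        self.points = sorted(self.points, key=lambda p: (p.part, p.v_mV))
        seen = set()
        for p in self.points:
            key = (p.part, round(p.v_mV, 6))
            if key in seen:
                raise ValueError(f"duplicate Rm point at part={p.part}, v={p.v_mV}")
            seen.add(key)

    def values(self, part: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        pts = [p for p in self.points if part is None or p.part == part]
        return (np.array([p.v_mV for p in pts]),
                np.array([p.rm_GOhm for p in pts]))


@dataclass
class VoltageRegions:
    """Allowed/disallowed voltage intervals around Rm singularities.

    Allowed regions are labelled from the depolarized end: 1 (plateau
    side), 2 (late repolarization), 3 (diastolic).
    """

    singular_voltages_mV: list[list[float]]
    disallowed: list[tuple[float, float]]
    allowed: list[tuple[float, float]]  # ordered depolarized → diastolic

    def allowed_region(self, label: int) -> tuple[float, float]:
        if not 1 <= label <= len(self.allowed):
            raise ConfigurationError(
                f"allowed region {label} does not exist "
                f"({len(self.allowed)} regions defined)")
        return self.allowed[label - 1]

    def is_allowed(self, v_mV: float) -> bool:
        return not any(lo <= v_mV <= hi for lo, hi in self.disallowed)


@dataclass
class RcCurve:
    """Interpolated Rm-vs-voltage curve within Allowed Region 2."""

    node_voltages_mV: np.ndarray
    node_rm_GOhm: np.ndarray
    dense_voltages_mV: np.ndarray
    dense_rm_GOhm: np.ndarray

    @property
    def D(self) -> int:
        return len(self.dense_voltages_mV)


@dataclass
class RdValue:
    """Scalar diastolic membrane resistance."""

    rd_GOhm: float
    v_mV: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_ap(trace: APTrace, prominence_mV: float = 1.0) -> APSegments:
    """Segment a beat at its spike peak, notch and dome.

    The trace is smoothed with a 3-sample moving median before extremum
    detection to suppress spurious extrema.  A trace without the
    notch/dome extrema (e.g. a monotone passive decay or a triangular AP)
    yields a degenerate segmentation whose single descending part is
    reported as part 3.
    """
    vm = medfilt(trace.vm, kernel_size=3)
    i_peak = int(np.argmax(vm))
    after = vm[i_peak:]
    minima, _ = find_peaks(-after, prominence=prominence_mV)
    t_end = float(trace.t[-1])
    peak = (float(trace.t[i_peak]), float(vm[i_peak]))

    if len(minima) == 0:
        return APSegments(boundaries=[peak], t_end=t_end, degenerate=True)
    i_notch = i_peak + int(minima[0])
    maxima, _ = find_peaks(after, prominence=prominence_mV)
    maxima = [i for i in maxima if i_peak + i > i_notch]
    if len(maxima) == 0:
        return APSegments(boundaries=[peak], t_end=t_end, degenerate=True)
    i_dome = i_peak + int(maxima[0])
    notch = (float(trace.t[i_notch]), float(vm[i_notch]))
    dome = (float(trace.t[i_dome]), float(vm[i_dome]))
    return APSegments(boundaries=[peak, notch, dome], t_end=t_end)


# ---------------------------------------------------------------------------
# Rm measurement
# ---------------------------------------------------------------------------

def rm_from_state(model: CellModel, state: np.ndarray,
                  hold_ms: float = 5.0) -> tuple[float, float]:
    """Dual-clamp Rm from a given pre-clamp state.

    Returns ``(rm_GOhm, delta_im)``; ``rm_GOhm`` is signed ±inf when the
    current difference is below the singular threshold.
    """
    v = float(state[model.vm_index])
    up = voltage_clamp(model, state, v + CLAMP_STEP_MV, hold_ms)
    dn = voltage_clamp(model, state, v - CLAMP_STEP_MV, hold_ms)
    delta_im = up.im_end_pA_per_pF - dn.im_end_pA_per_pF
    if abs(delta_im) < SINGULAR_DELTA_IM:
        return math.inf, delta_im
    rm = (2 * CLAMP_STEP_MV / delta_im) / NORMALIZATION_CAPACITANCE_PF
    return rm, delta_im


def measure_rm(model: CellModel, beat_state: np.ndarray,
               protocol: StimulusProtocol, v_mV: float, part: int,
               recording: BeatRecording | None = None,
               segments: APSegments | None = None) -> RmPoint:
    """Measure Rm at voltage ``v_mV`` within the given AP part."""
    state = run_to_voltage(model, beat_state, protocol, v_mV, part,
                           recording=recording, segments=segments)
    rm, delta_im = rm_from_state(model, state)
    return RmPoint(v_mV=v_mV, rm_GOhm=rm, part=part, delta_im=delta_im)


def _paced(model: CellModel, protocol: StimulusProtocol,
           paced: PacedBeat | None) -> tuple[PacedBeat, APSegments]:
    if paced is None:
        paced = pace_to_steady_state(model, protocol)
    return paced, segment_ap(paced.trace)


def _part_voltage_spans(recording: BeatRecording,
                        segments: APSegments) -> dict[int, tuple[float, float]]:
    spans = {}
    for part in segments.parts():
        t0, t1 = segments.time_window(part)
        mask = (recording.t >= t0 - 1e-9) & (recording.t <= t1 + 1e-9)
        vv = recording.vm[mask]
        spans[part] = (float(vv.min()), float(vv.max()))
    return spans


def compute_rm_profile(model: CellModel, protocol: StimulusProtocol,
                       voltage_step_mV: float,
                       paced: PacedBeat | None = None) -> RmProfile:
    """Rm at every multiple of ``voltage_step_mV`` within each part's span."""
    if voltage_step_mV <= 0:
        raise ValueError("voltage step must be positive")
    paced, segments = _paced(model, protocol, paced)
    rec = paced.recording
    spans = _part_voltage_spans(rec, segments)
    points: list[RmPoint] = []
    for part, (lo, hi) in spans.items():
        grid = np.arange(math.ceil(lo / voltage_step_mV),
                         math.floor(hi / voltage_step_mV) + 1) * voltage_step_mV
        for v in grid:
            try:
                points.append(measure_rm(model, paced.beat_start_state, protocol,
                                         float(v), part, recording=rec,
                                         segments=segments))
            except NotReachableError:
                continue
    return RmProfile(points=points, model_id=model.name)


def find_singularities(model: CellModel, protocol: StimulusProtocol,
                       scan_step_mV: float = 1.0,
                       paced: PacedBeat | None = None) -> list[float]:
    """Voltages at which ΔIm crosses zero, refined to 0.1 mV by bisection."""
    if scan_step_mV > 1.0:
        raise ValueError("scan step must be <= 1 mV")
    paced, segments = _paced(model, protocol, paced)
    rec = paced.recording

    def delta_im(v: float, part: int) -> float:
        state = run_to_voltage(model, paced.beat_start_state, protocol, v,
                               part, recording=rec, segments=segments)
        _, d = rm_from_state(model, state)
        return d

    singular: list[float] = []
    spans = _part_voltage_spans(rec, segments)
    for part, (lo, hi) in spans.items():
        if hi - lo < 2 * scan_step_mV:
            continue
        grid = np.arange(lo + scan_step_mV / 2, hi, scan_step_mV)
        d = np.array([delta_im(float(v), part) for v in grid])
        for i in np.nonzero(d[:-1] * d[1:] < 0)[0]:
            a, b = float(grid[i]), float(grid[i + 1])
            da = d[i]
            while b - a > SINGULARITY_TOL_MV:
                mid = 0.5 * (a + b)
                dm = delta_im(mid, part)
                if dm == 0.0:
                    a = b = mid
                    break
                if (da < 0) == (dm < 0):
                    a, da = mid, dm
                else:
                    b = mid
            singular.append(0.5 * (a + b))
    return sorted(singular)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def define_regions(singularities_per_model: list[list[float]],
                   margin_mV: float = REGION_MARGIN_MV,
                   span_mV: tuple[float, float] | None = None) -> VoltageRegions:
    """Cluster singularities from all models into disallowed intervals.

    Each singularity contributes a closed interval ±``margin_mV`` around
    it; overlapping intervals are merged.  Allowed regions are the
    complementary intervals within the AP voltage span, labelled 1..k from
    the depolarized end.
    """
    if margin_mV <= 0:
        raise ValueError("margin must be positive")
    if not singularities_per_model:
        raise ConfigurationError("at least one singularity list is required")
    all_s = sorted(v for lst in singularities_per_model for v in lst)

    if span_mV is None:
        if all_s:
            span_mV = (min(all_s) - 25.0, max(all_s) + 25.0)
        else:
            raise ConfigurationError(
                "span_mV is required when no singularities are provided")
    lo_span, hi_span = span_mV

    disallowed: list[tuple[float, float]] = []
    if not all_s:
        warnings.warn("no singularities detected: whole span allowed, "
                      "region labels assigned by voltage thirds")
        third = (hi_span - lo_span) / 3
        allowed = [(hi_span - third, hi_span),
                   (lo_span + third, hi_span - third),
                   (lo_span, lo_span + third)]
        return VoltageRegions(singularities_per_model, [], allowed)

    for s in all_s:
        iv = (s - margin_mV, s + margin_mV)
        if disallowed and iv[0] <= disallowed[-1][1]:
            disallowed[-1] = (disallowed[-1][0], iv[1])
        else:
            disallowed.append(iv)

    allowed: list[tuple[float, float]] = []
    cursor = lo_span
    for lo, hi in disallowed:
        if lo > cursor:
            allowed.append((cursor, min(lo, hi_span)))
        cursor = max(cursor, hi)
    if cursor < hi_span:
        allowed.append((cursor, hi_span))
    allowed = [iv for iv in allowed if iv[1] - iv[0] > 1e-9]
    allowed.sort(key=lambda iv: -iv[1])  # label 1 = most depolarized
    return VoltageRegions(singularities_per_model, disallowed, allowed)


# ---------------------------------------------------------------------------
# Rc curve and Rd
# ---------------------------------------------------------------------------

def _part_for_voltage(spans: dict[int, tuple[float, float]], v: float) -> int:
    # prefer the repolarization tail, where the Rc/Rd voltages live
    for part in (3, 2, 1):
        if part in spans:
            lo, hi = spans[part]
            if lo <= v <= hi:
                return part
    raise NotReachableError(f"{v} mV not within any AP part span")


def region2_node_voltages(regions: VoltageRegions,
                          node_spacing_mV: float = 5.0) -> np.ndarray:
    """Raw sample voltages: every multiple of the spacing inside Allowed Region 2."""
    lo, hi = regions.allowed_region(2)
    return np.arange(math.ceil(lo / node_spacing_mV),
                     math.floor(hi / node_spacing_mV) + 1) * node_spacing_mV


def build_rc_curve(model: CellModel, protocol: StimulusProtocol,
                   regions: VoltageRegions, node_spacing_mV: float = 5.0,
                   dense_spacing_mV: float = 0.5,
                   paced: PacedBeat | None = None,
                   node_voltages: np.ndarray | None = None,
                   dense_voltages: np.ndarray | None = None) -> RcCurve:
    """Measure Rm at 5 mV-spaced nodes in Allowed Region 2 and interpolate.

    A shape-preserving piecewise-cubic (PCHIP) interpolant connects the
    nodes; the densely sampled curve (default 0.5 mV spacing) is what the
    RMSE_Rc objective compares.  When fitting, the reference's node and
    dense grids are reused for the candidate so both curves share the same
    D abscissae.
    """
    paced, segments = _paced(model, protocol, paced)
    rec = paced.recording
    spans = _part_voltage_spans(rec, segments)
    if node_voltages is None:
        node_voltages = region2_node_voltages(regions, node_spacing_mV)
    node_voltages = np.asarray(node_voltages, dtype=float)
    if len(node_voltages) < 2:
        raise ConfigurationError(
            "Allowed Region 2 must span at least two node spacings")

    vs, rms = [], []
    for v in node_voltages:
        part = _part_for_voltage(spans, float(v))
        pt = measure_rm(model, paced.beat_start_state, protocol, float(v),
                        part, recording=rec, segments=segments)
        if pt.singular:
            warnings.warn(f"singular Rm at node {v} mV dropped from Rc curve")
            continue
        vs.append(pt.v_mV)
        rms.append(pt.rm_GOhm)
    if len(vs) < 2:
        raise ConfigurationError("fewer than two finite Rc nodes")
    order = np.argsort(vs)
    vs = np.array(vs)[order]
    rms = np.array(rms)[order]
    interp = PchipInterpolator(vs, rms)
    if dense_voltages is None:
        n_dense = int(math.floor((vs[-1] - vs[0]) / dense_spacing_mV)) + 1
        dense_voltages = vs[0] + np.arange(n_dense) * dense_spacing_mV
    dense_voltages = np.asarray(dense_voltages, dtype=float)
    return RcCurve(node_voltages_mV=vs, node_rm_GOhm=rms,
                   dense_voltages_mV=dense_voltages,
                   dense_rm_GOhm=interp(dense_voltages))


def diastolic_voltage_range(trace: APTrace) -> tuple[float, float]:
    """Voltage range of the diastolic (resting) phase of the beat.

    Taken as the voltages below the 90 %-repolarization level, i.e. the
    bottom tenth of the AP amplitude.
    """
    v_peak = float(np.max(trace.vm))
    v_min = float(np.min(trace.vm))
    return v_min, v_peak - 0.9 * (v_peak - v_min)


def measure_rd(model: CellModel, beat_state: np.ndarray,
               protocol: StimulusProtocol, regions: VoltageRegions,
               quantile: float = 0.5, paced: PacedBeat | None = None,
               at_voltage: float | None = None) -> RdValue:
    """Diastolic Rm in Allowed Region 3.

    Measured at the ``quantile`` point (default midpoint) of the
    intersection of Allowed Region 3 with the beat's diastolic voltage
    range.  ``at_voltage`` overrides the measurement voltage so that a
    candidate can be probed at the reference's diastolic voltage.
    """
    paced, segments = _paced(model, protocol, paced)
    if at_voltage is None:
        lo3, hi3 = regions.allowed_region(3)
        d_lo, d_hi = diastolic_voltage_range(paced.trace)
        lo, hi = max(lo3, d_lo), min(hi3, d_hi)
        if hi <= lo:
            raise ConfigurationError(
                "Allowed Region 3 does not intersect the diastolic range")
        at_voltage = lo + quantile * (hi - lo)
    part = segments.parts()[-1]
    pt = measure_rm(model, paced.beat_start_state, protocol, float(at_voltage),
                    part, recording=paced.recording, segments=segments)
    return RdValue(rd_GOhm=pt.rm_GOhm, v_mV=float(at_voltage))
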