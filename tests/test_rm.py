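"""Membrane-resistance analysis: segmentation, the dual-clamp Rm oracle,
singularity detection, region construction, Rc curves and Rd."""

import math

import numpy as np
import pytest

from cardiofit.exceptions import ConfigurationError
from cardiofit.io import CUBIC_SINGULARITY_MV, make_fixture
from cardiofit.models import (build_passive_membrane, build_static_membrane)
from cardiofit.pacing import StimulusProtocol
from cardiofit import rm


def brute_force_extrema(vm, prominence=1.0):
    """Independent O(n·w) local-extremum scan used as a segmentation oracle."""
    minima, maxima = [], []
    for i in range(1, len(vm) - 1):
        if vm[i] >= vm[i - 1] and vm[i] >= vm[i + 1]:
            left = vm[:i].min() if i else vm[i]
            right = vm[i + 1:].min()
            if vm[i] - max(left, right) >= 0:  # candidate local max
                maxima.append(i)
        if vm[i] <= vm[i - 1] and vm[i] <= vm[i + 1]:
            minima.append(i)
    # apply prominence by comparing against neighbouring extremes
    return minima, maxima


class TestSegmentation:
    def test_tnnp_boundaries_match_extremum_scan(self, tnnp_paced,
                                                 tnnp_segments):
        """Notch and dome agree with a brute-force scan of local extrema."""
        from scipy.signal import medfilt
        vm = medfilt(tnnp_paced.trace.vm, kernel_size=3)
        t = tnnp_paced.trace.t
        i_peak = int(np.argmax(vm))
        minima, maxima = brute_force_extrema(vm)
        notch_candidates = [i for i in minima
                            if i > i_peak and vm[i] < vm[i_peak] - 1.0]
        i_notch = notch_candidates[0]
        dome_candidates = [i for i in maxima
                           if i > i_notch and vm[i] > vm[i_notch] + 1.0]
        i_dome = dome_candidates[0]
        (t_peak, _), (t_notch, _), (t_dome, _) = tnnp_segments.boundaries
        assert t_peak == t[i_peak]
        assert abs(t_notch - t[i_notch]) <= 1.0
        assert abs(t_dome - t[i_dome]) <= 1.0

    def test_synthetic_spike_notch_dome_waveform(self):
        """Boundaries land within one sample of the constructed extrema."""
        fix = make_fixture("spike_notch_dome_trace")
        seg = rm.segment_ap(fix.obj)
        assert not seg.degenerate
        for (t_found, _), key in zip(seg.boundaries, ("peak", "notch", "dome")):
            assert abs(t_found - fix.ground_truth[key][0]) <= 1.0

    def test_part_index_partitions_the_beat(self, tnnp_segments):
        t_peak = tnnp_segments.boundaries[0][0]
        parts = [tnnp_segments.part_index(t)
                 for t in np.linspace(t_peak, tnnp_segments.t_end, 50)]
        assert set(parts) == {1, 2, 3}
        assert parts == sorted(parts)


class TestRmMeasurement:
    def test_passive_membrane_rm_is_exact(self, passive_model):
        for v in (-80.0, -60.0, -30.0, 0.0):
            rm_val, _ = rm.rm_from_state(passive_model, np.array([v]))
            assert rm_val == pytest.approx(1.0, abs=1e-4)

    def test_static_cubic_membrane_matches_closed_form(self):
        """Oracle equivalence: Rm == 20/(I(v+10)-I(v-10)) normalized, <1e-6."""
        fix = make_fixture("cubic_static")
        model, truth = fix.obj, fix.ground_truth
        a, (e1, e2, e3) = truth["a"], truth["roots"]

        def current(v):
            return a * (v - e1) * (v - e2) * (v - e3)

        for v in (-80.0, -50.0, -20.0, 10.0):
            expected = (20.0 / (current(v + 10) - current(v - 10))) / 180.0
            measured, _ = rm.rm_from_state(model, np.array([v]))
            assert measured == pytest.approx(expected, rel=1e-6)

    def test_capacitance_normalization_invariance(self):
        """Equal normalized resistance, different capacitance → equal Rm."""
        small = build_passive_membrane(2.0, -85.0, 90.0)
        large = build_passive_membrane(2.0, -85.0, 360.0)
        rm_small, _ = rm.rm_from_state(small, np.array([-70.0]))
        rm_large, _ = rm.rm_from_state(large, np.array([-70.0]))
        assert rm_small == pytest.approx(rm_large, rel=1e-12)
        assert rm_small == pytest.approx(2.0, abs=1e-4)

    def test_profile_of_passive_membrane_is_constant(self, passive_model):
        profile = rm.compute_rm_profile(passive_model, StimulusProtocol(n_beats=2),
                                        5.0)
        _, values = profile.values()
        assert len(values) > 3
        assert np.allclose(values, 1.0, atol=1e-4)


class TestSingularities:
    def test_passive_membrane_has_none(self, passive_model):
        sing = rm.find_singularities(passive_model, StimulusProtocol(n_beats=2))
        assert sing == []

    def test_engineered_linear_delta_im_root_is_located(self):
        """ΔIm(v) = c (v - v0) → exactly one singularity at v0 ± 0.1 mV."""
        v0, c, b = -60.0, 0.2, 0.02

        def current(v):
            return (c / 40.0) * (v - v0) ** 2 + b

        model = build_static_membrane(current, name="quadratic_static",
                                      initial_mV=-40.0)
        # short cycle: the quadratic decay steepens far below v0
        sing = rm.find_singularities(
            model, StimulusProtocol(cycle_length_ms=250.0, n_beats=1))
        assert len(sing) == 1
        assert abs(sing[0] - v0) <= 0.1

    def test_cubic_fixture_has_one_sign_change_at_documented_root(self):
        fix = make_fixture("cubic_static")
        a, (e1, e2, e3) = fix.ground_truth["a"], fix.ground_truth["roots"]

        def delta_im(v):
            i = lambda u: a * (u - e1) * (u - e2) * (u - e3)
            return i(v + 10) - i(v - 10)

        grid = np.arange(-90.0, 25.0, 0.5)
        d = np.array([delta_im(v) for v in grid])
        crossings = np.nonzero(d[:-1] * d[1:] < 0)[0]
        assert len(crossings) == 1
        assert abs(grid[crossings[0]] - CUBIC_SINGULARITY_MV) < 1.0

    def test_tnnp_has_singularities_bracketing_negative_rm(
            self, tnnp_model, protocol, tnnp_paced, tnnp_singularities,
            tnnp_segments):
        assert len(tnnp_singularities) >= 2
        lo, hi = min(tnnp_singularities), max(tnnp_singularities)
        mid = 0.5 * (lo + hi)
        pt = rm.measure_rm(tnnp_model, tnnp_paced.beat_start_state, protocol,
                           mid, 3, recording=tnnp_paced.recording,
                           segments=tnnp_segments)
        assert pt.rm_GOhm < 0


class TestRegions:
    def test_single_singularity_margin_arithmetic(self):
        regions = rm.define_regions([[-40.0]], span_mV=(-85.0, 30.0))
        assert regions.disallowed == [(-45.0, -35.0)]

    def test_overlapping_clusters_merge(self):
        regions = rm.define_regions([[-40.0], [-35.0]], span_mV=(-85.0, 30.0))
        assert regions.disallowed == [(-45.0, -30.0)]

    def test_default_margin_is_five_millivolts(self):
        assert rm.REGION_MARGIN_MV == 5.0

    def test_labels_run_from_plateau_to_diastole(self):
        regions = rm.define_regions([[-10.0, -60.0]], span_mV=(-85.0, 30.0))
        r1, r2, r3 = (regions.allowed_region(i) for i in (1, 2, 3))
        assert r1[0] > r2[1] >= r2[0] > r3[1]

    def test_region_soundness_near_singularities(self, rng):
        """No allowed voltage lies within (margin - 0.1) of a singularity."""
        for _ in range(50):
            sing = sorted(rng.uniform(-80, 20, size=rng.integers(1, 6)))
            regions = rm.define_regions([list(sing)], span_mV=(-90.0, 40.0))
            for s in sing:
                for off in (-4.9, 0.0, 4.9):
                    assert not regions.is_allowed(s + off)

    def test_empty_singularity_input_warns_and_splits_by_thirds(self):
        with pytest.warns(UserWarning):
            regions = rm.define_regions([[]], span_mV=(-90.0, 30.0))
        assert len(regions.allowed) == 3
        assert regions.disallowed == []


class TestRcCurveAndRd:
    # two synthetic singularities placing Allowed Region 2 inside the
    # passive beat's reachable span [-85, -45]
    PASSIVE_REGIONS = rm.define_regions([[-50.0, -78.0]],
                                        span_mV=(-85.0, -40.0))

    def test_passive_rc_curve_is_flat(self, passive_model):
        curve = rm.build_rc_curve(passive_model, StimulusProtocol(n_beats=2),
                                  self.PASSIVE_REGIONS)
        assert np.allclose(curve.dense_rm_GOhm, 1.0, atol=1e-4)
        assert curve.D >= len(curve.node_voltages_mV)

    def test_interpolant_reproduces_linear_data_exactly(self):
        """Shape-preserving interpolation is exact on collinear nodes."""
        from scipy.interpolate import PchipInterpolator
        v = np.array([-55.0, -50.0, -45.0, -40.0])
        r = 0.02 * v + 1.5
        dense = np.arange(-55.0, -40.0, 0.5)
        assert np.allclose(PchipInterpolator(v, r)(dense), 0.02 * dense + 1.5,
                           atol=1e-9)

    def test_interpolant_passes_through_nodes(self, tnnp_model, protocol,
                                              tnnp_paced, tnnp_regions):
        curve = rm.build_rc_curve(tnnp_model, protocol, tnnp_regions,
                                  paced=tnnp_paced)
        for v, r in zip(curve.node_voltages_mV, curve.node_rm_GOhm):
            j = np.nonzero(np.isclose(curve.dense_voltages_mV, v))[0]
            if len(j):
                assert curve.dense_rm_GOhm[j[0]] == pytest.approx(r, abs=1e-12)

    def test_rd_of_passive_membrane_is_configured_resistance(self,
                                                             passive_model):
        rd = rm.measure_rd(passive_model, np.array([-85.0]),
                           StimulusProtocol(n_beats=2), self.PASSIVE_REGIONS)
        assert rd.rd_GOhm == pytest.approx(1.0, abs=1e-4)

    def test_rd_voltage_is_region3_midpoint(self, tnnp_model, protocol,
                                            tnnp_paced, tnnp_regions):
        rd = rm.measure_rd(tnnp_model, tnnp_paced.beat_start_state, protocol,
                           tnnp_regions, quantile=0.5, paced=tnnp_paced)
        lo3, hi3 = tnnp_regions.allowed_region(3)
        d_lo, d_hi = rm.diastolic_voltage_range(tnnp_paced.trace)
        lo, hi = max(lo3, d_lo), min(hi3, d_hi)
        assert rd.v_mV == pytest.approx(0.5 * (lo + hi))
        assert math.isfinite(rd.rd_GOhm) and rd.rd_GOhm > 0

    def test_profile_is_continuous_within_allowed_region_two(
            self, tnnp_model, protocol, tnnp_paced, tnnp_regions,
            tnnp_segments):
        """Rm changes smoothly (no sign flip) across Allowed Region 2."""
        lo, hi = tnnp_regions.allowed_region(2)
        grid = np.arange(math.ceil(lo), math.floor(hi) + 1, 1.0)
        values = [rm.measure_rm(tnnp_model, tnnp_paced.beat_start_state,
                                protocol, float(v), 3,
                                recording=tnnp_paced.recording,
                                segments=tnnp_segments).rm_GOhm
                  for v in grid]
        values = np.array(values)
        assert np.all(np.isfinite(values))
        assert np.all(values < 0) or np.all(values > 0)
        assert np.max(np.abs(np.diff(values))) < 1.0
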