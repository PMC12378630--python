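"""Kymogram extraction, axis placement, trace, cycles, and phase detection."""

import numpy as np
import pytest

from mrkymo.kymogram import (
    DiaphragmTrace,
    Landmarks,
    detect_extreme_phases,
    extract_diaphragm_trace,
    extract_xt,
    extract_yt,
    flag_inconsistent_cycles,
    place_axes,
    segment_cycles,
)
from mrkymo.phantom import breathing_phase, diaphragm_apex_y_mm, mm_to_px
from mrkymo.preprocess import preprocess_pipeline
from mrkymo.series import Plane
from mrkymo.session import phantom_landmarks, phantom_search_band


@pytest.fixture(scope="module")
def processed_noiseless(noiseless_coronal):
    config, series, truth = noiseless_coronal
    pre = preprocess_pipeline(series, 512, with_overlay=False)
    return config, pre, truth


def _scaled_band(config, factor, max_scale=1.0):
    lo, hi = phantom_search_band(config, max_scale)
    return (int(factor * (lo + 0.5) - 0.5), int(np.ceil(factor * (hi + 0.5) - 0.5)))


def _trace_from(config, pre, factor=512 / 192, **kw):
    lm = phantom_landmarks(config).scaled(factor)
    col = place_axes(lm, Plane.CORONAL).hf_right_column
    yt = extract_yt(pre.denoised, pre.contours, col)
    return extract_diaphragm_trace(yt, _scaled_band(config, factor, kw.pop("max_scale", 1.0)), **kw)


class TestExtraction:
    def test_yt_matches_direct_frame_indexing(self, processed_noiseless):
        _, pre, _ = processed_noiseless
        k = extract_yt(pre.denoised, pre.contours, 200)
        assert np.array_equal(k.values[:, 4], pre.denoised.frames[4][:, 200])
        assert np.array_equal(k.contour_values[:, 4], pre.contours.frames[4][:, 200])

    def test_xt_matches_direct_frame_indexing(self, processed_noiseless):
        _, pre, _ = processed_noiseless
        k = extract_xt(pre.denoised, pre.contours, 300)
        assert np.array_equal(k.values[:, 2], pre.denoised.frames[2][300, :])

    def test_stacking_all_columns_reconstructs_frames(self, processed_noiseless):
        _, pre, _ = processed_noiseless
        cols = [extract_yt(pre.denoised, pre.contours, x).values for x in range(0, 512, 64)]
        rebuilt = np.stack(cols, axis=-1)  # (space, time, cols)
        assert np.array_equal(rebuilt[:, 3, :], pre.denoised.frames[3][:, ::64])

    def test_static_phantom_time_columns_identical(self, static_phantom):
        _, series, _ = static_phantom
        pre = preprocess_pipeline(series.with_frames(series.frames[:4]), 256,
                                  with_overlay=False)
        k = extract_yt(pre.denoised, pre.contours, 128)
        assert np.allclose(k.values, k.values[:, :1])

    def test_out_of_bounds_rejected(self, processed_noiseless):
        _, pre, _ = processed_noiseless
        with pytest.raises(IndexError):
            extract_yt(pre.denoised, pre.contours, 512)
        with pytest.raises(IndexError):
            extract_xt(pre.denoised, pre.contours, -1)

    def test_diaphragm_oscillation_peak_to_peak(self, processed_noiseless):
        """Lung/liver boundary oscillates by amplitude/spacing px on the y-t kymogram."""
        config, pre, _ = processed_noiseless
        trace = _trace_from(config, pre)
        spacing = 500 / 512
        p2p = (np.nanmax(trace.y_position) - np.nanmin(trace.y_position)) * spacing
        assert p2p == pytest.approx(config.amplitude_hf_right_mm, abs=1.5 * spacing)


class TestPlaceAxes:
    def _coronal_landmarks(self, **overrides):
        pts = {
            "right_dome_end_1": (100, 150),
            "right_dome_end_2": (180, 150),
            "left_dome_end_1": (300, 150),
            "left_dome_end_2": (360, 150),
            "right_diaphragm_lateral_inferior_edge": (90, 300),
            "right_thorax_uppermost": (140, 100),
        }
        pts.update(overrides)
        return Landmarks(points=pts)

    def test_hf_column_is_midpoint(self):
        axes = place_axes(self._coronal_landmarks(), Plane.CORONAL)
        assert axes.hf_right_column == 140
        assert axes.hf_left_column == 330

    def test_rl_row_is_midpoint_of_y(self):
        axes = place_axes(self._coronal_landmarks(), Plane.CORONAL)
        assert axes.rl_row == 200

    def test_midpoint_rounds_half_up(self):
        axes = place_axes(
            self._coronal_landmarks(right_dome_end_2=(181, 150)), Plane.CORONAL
        )
        assert axes.hf_right_column == 141  # (100+181)/2 = 140.5 -> 141

    def test_coincident_landmarks(self):
        axes = place_axes(
            self._coronal_landmarks(right_dome_end_1=(180, 150)), Plane.CORONAL
        )
        assert axes.hf_right_column == 180

    def test_missing_landmark_named(self):
        pts = self._coronal_landmarks().points
        del pts["right_thorax_uppermost"]
        with pytest.raises(KeyError, match="right_thorax_uppermost"):
            place_axes(Landmarks(points=pts), Plane.CORONAL)

    def test_sagittal_ap_row(self):
        lm = Landmarks(points={
            "dome_end_1": (80, 260), "dome_end_2": (160, 260),
            "diaphragm_dorsalmost_inferior_edge": (70, 280),
            "thoracic_cavity_uppermost": (120, 100),
        })
        axes = place_axes(lm, Plane.SAGITTAL_RIGHT)
        assert axes.ap_row == 190

    def test_out_of_frame_landmark_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            Landmarks(points={"a": (200, 10)}, frame_shape=(100, 100))


class TestDiaphragmTrace:
    def test_noiseless_trace_matches_analytic_all_times(self, processed_noiseless):
        config, pre, _ = processed_noiseless
        trace = _trace_from(config, pre)
        factor = 512 / 192
        for t in np.nonzero(trace.valid_mask)[0]:
            phi = float(breathing_phase(config, t * config.frame_interval_s))
            # trace runs at the dome-apex column: curvature term ~0 there
            expected = factor * (mm_to_px(config, diaphragm_apex_y_mm(config, phi)) + 0.5) - 0.5
            assert trace.y_position[t] == pytest.approx(expected, abs=1.0), f"t={t}"

    def test_static_phantom_constant_trace(self, static_phantom):
        config, series, _ = static_phantom
        pre = preprocess_pipeline(series.with_frames(series.frames[:6]), 512,
                                  with_overlay=False)
        trace = _trace_from(config, pre)
        y = trace.y_position[trace.valid_mask]
        assert np.ptp(y) <= 0.5

    def test_band_without_diaphragm_errors(self, processed_noiseless):
        config, pre, _ = processed_noiseless
        lm = phantom_landmarks(config).scaled(512 / 192)
        col = place_axes(lm, Plane.CORONAL).hf_right_column
        yt = extract_yt(pre.denoised, pre.contours, col)
        with pytest.raises(ValueError):
            extract_diaphragm_trace(yt, (200, 230))  # mid-lung tissue-free zone

    def test_bad_band_bounds_rejected(self, processed_noiseless):
        config, pre, _ = processed_noiseless
        yt = extract_yt(pre.denoised, pre.contours, 200)
        with pytest.raises(ValueError, match="band"):
            extract_diaphragm_trace(yt, (400, 9999))


def _make_trace(y, spacing=500 / 512):
    y = np.asarray(y, float)
    return DiaphragmTrace(
        y_position=y,
        valid_mask=np.ones(len(y), bool),
        spatial_spacing_mm=spacing,
        time_spacing_s=0.6,
    )


def _cyclic_trace(amplitudes, period=10):
    t = np.arange(period)
    phi = np.sin(np.pi * t / period) ** 2
    return _make_trace(np.concatenate([100 + a * phi for a in amplitudes]))


class TestFlagInconsistentCycles:
    def test_identical_cycles_nothing_excluded(self):
        out = flag_inconsistent_cycles(_cyclic_trace([60.0] * 8))
        assert out.excluded_intervals == []

    def test_shallow_cycle_excluded_exactly(self):
        out = flag_inconsistent_cycles(_cyclic_trace([60, 60, 60 * 0.3, 60, 60, 60, 60, 60]))
        assert len(out.excluded_intervals) == 1
        t0, t1 = out.excluded_intervals[0]
        assert t0 <= 20 < 30 <= t1  # brackets cycle 2

    def test_uniform_scaling_invariant(self):
        out = flag_inconsistent_cycles(_cyclic_trace([25.0] * 8))
        assert out.excluded_intervals == []

    def test_fewer_than_three_cycles_warns(self):
        with pytest.warns(UserWarning, match="cycles"):
            out = flag_inconsistent_cycles(_cyclic_trace([60, 60]))
        assert out.excluded_intervals == []

    def test_segmentation_counts_cycles(self):
        cycles = segment_cycles(_cyclic_trace([60.0] * 8))
        assert len(cycles) == 8


class TestDetectExtremePhases:
    def test_phantom_phases_equal_ground_truth(self, processed_noiseless):
        config, pre, truth = processed_noiseless
        trace = flag_inconsistent_cycles(_trace_from(config, pre))
        phases = detect_extreme_phases(trace)
        assert phases.t_end_insp == truth.t_end_insp
        assert phases.t_end_exp == truth.t_end_exp

    def test_monotone_trace_selects_endpoints_with_warning(self):
        trace = _make_trace(np.linspace(100, 160, 20))
        with pytest.warns(UserWarning, match="monotone"):
            phases = detect_extreme_phases(trace)
        assert phases.t_end_insp == 19
        assert phases.t_end_exp == 0

    def test_amplified_cycle_kept_when_k_huge_wins_end_insp(self):
        y = _cyclic_trace([60, 60, 60, 90, 60, 60, 60, 60])
        kept = flag_inconsistent_cycles(y, k=1e9)
        assert kept.excluded_intervals == []
        phases = detect_extreme_phases(kept)
        assert 30 <= phases.t_end_insp < 40

    def test_excluded_interval_not_selected(self):
        trace = _cyclic_trace([60, 60, 60, 90, 60, 60, 60, 60])
        trace.excluded_intervals = [(30, 40)]
        phases = detect_extreme_phases(trace)
        assert not 30 <= phases.t_end_insp < 40

    def test_tie_broken_to_earliest_cycle(self):
        trace = _cyclic_trace([60.0] * 8)
        phases = detect_extreme_phases(trace)
        assert phases.t_end_insp == 5  # first cycle's sampled peak
        assert phases.t_end_exp == 0

    def test_all_excluded_errors(self):
        trace = _cyclic_trace([60.0] * 4)
        trace.excluded_intervals = [(0, 40)]
        with pytest.raises(ValueError):
            detect_extreme_phases(trace)


class TestPhaseRecoveryProperty:
    def test_phase_recovery_over_randomised_phantoms(self, phase_study_result):
        """Detected phases match truth exactly in >=95% of runs, within 1 frame always."""
        assert phase_study_result.exact_fraction >= 0.95
        assert phase_study_result.within_one_fraction == 1.0

    def test_exclusion_sensitivity_and_specificity(self, cycle_flag_result):
        """Injected inconsistent cycles flagged >=95%; no false flags on clean runs."""
        assert cycle_flag_result.sensitivity >= 0.95
        assert cycle_flag_result.n_false_flag_runs == 0
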