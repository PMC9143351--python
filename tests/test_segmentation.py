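import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrecover.segmentation import (
    GaitEvents,
    InsufficientStridesError,
    assign_step_sides,
    detect_events,
    detect_stair_strides,
    detect_walking_steps,
    extract_middle_stride,
    lowpass_filter,
    segment_trial,
    strides_from_steps,
)
from gaitrecover.synthetic_cohort import ANGLE_CHANNELS, generate_trial

from conftest import make_profile

FS = 60.0


def sine(freq, fs=FS, duration=10.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestLowpassFilter:
    @given(st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_dc_passthrough(self, c):
        out = lowpass_filter(np.full(200, c), FS)
        np.testing.assert_allclose(out, c, atol=1e-8 * max(1.0, abs(c)))

    def test_1hz_attenuation_below_1pct(self):
        out = lowpass_filter(sine(1.0), FS)
        # ignore filter edges when measuring amplitude
        core = out[60:-60]
        assert np.abs(core).max() > 0.99

    def test_25hz_attenuation_above_90pct(self):
        out = lowpass_filter(sine(25.0), FS)
        core = out[60:-60]
        assert np.abs(core).max() < 0.1

    def test_zero_phase_no_peak_shift(self):
        # a slow gaussian bump keeps its peak position under zero-phase filtering
        idx = np.arange(600, dtype=float)
        x = np.exp(-0.5 * ((idx - 300) / 30.0) ** 2)
        out = lowpass_filter(x, FS)
        assert np.argmax(out) == 300

    def test_same_length(self):
        x = np.random.default_rng(0).normal(size=333)
        assert len(lowpass_filter(x, FS)) == 333

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_filter(np.zeros(10), FS)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            lowpass_filter(np.zeros(100), sample_rate=10.0, cutoff=6.0)

    def test_near_idempotent_on_gait_signal(self, walk_trial):
        once = lowpass_filter(walk_trial.angles["knee_flex_ext"], FS)
        twice = lowpass_filter(once, FS)
        rel = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert rel < 0.01


class TestDetectWalkingSteps:
    def test_all_zero_series(self):
        assert detect_walking_steps(np.zeros(500), FS) == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detect_walking_steps(np.array([]), FS)

    def test_planted_steps_recovered(self):
        profile = make_profile()
        trial = generate_trial(profile, "walk", "w6", n_cycles=6, seed=4)
        detected = detect_walking_steps(trial.accel_ap, FS)
        truth = trial.true_events.step_indices
        assert len(detected) == 12
        for d, t in zip(detected, truth):
            assert abs(d - t) <= 2

    def test_close_peaks_larger_kept(self):
        # brute force over the candidates: peaks of 5 and 7, 3 samples apart,
        # violate the 0.4 s minimum separation -> only the larger survives
        x = np.zeros(200)
        x[30] = 5.0
        x[33] = 7.0
        detected = detect_walking_steps(x, FS, min_step_interval=0.4)
        assert detected == [33]


class TestAssignStepSides:
    def test_clean_alternating_pattern(self):
        ml = np.zeros(300)
        steps = [30, 60, 90, 120]
        for k, idx in enumerate(steps):
            ml[idx - 3 : idx + 4] = 1.0 if k % 2 == 0 else -1.0
        sides = assign_step_sides(steps, ml, FS)
        assert sides == ["left", "right", "left", "right"]

    def test_zero_ml_tie_defaults(self):
        sides = assign_step_sides([50], np.zeros(100), FS, default_side="right")
        assert sides == ["right"]

    def test_window_truncated_at_edges(self):
        ml = np.ones(20)
        assert assign_step_sides([0, 19], ml, FS) == ["left", "left"]

    def test_out_of_bounds_index_rejected(self):
        with pytest.raises(ValueError):
            assign_step_sides([500], np.zeros(100), FS)

    def test_planted_sides_recovered(self):
        correct = total = 0
        for seed in range(10):
            profile = make_profile()
            trial = generate_trial(profile, "walk", "w6", seed=seed)
            sides = assign_step_sides(
                trial.true_events.step_indices, trial.accel_ml, FS
            )
            for got, want in zip(sides, trial.true_events.step_sides):
                total += 1
                correct += got == want
        assert correct / total >= 0.95


class TestDetectStairStrides:
    def test_monotone_series_no_extrema(self):
        assert detect_stair_strides(np.arange(100, dtype=float), FS) == []

    def test_planted_strides_recovered(self):
        profile = make_profile()
        trial = generate_trial(profile, "stairs_up", "w6", n_cycles=6, seed=4)
        intervals = detect_stair_strides(trial.tibia_accel_x["left"], FS)
        truth = trial.true_events.stride_bounds["left"]
        assert len(intervals) == 5
        for (ds, de), (ts, te) in zip(intervals, truth):
            assert abs(ds - ts) <= 2 and abs(de - te) <= 2

    def test_leading_max_without_min_not_boundary(self):
        # first local max has no preceding local min -> excluded; the two
        # qualifying boundaries delimit exactly one stride
        x = np.zeros(120)
        x[10] = 5.0  # max with no min before it
        x[30] = -5.0
        x[50] = 5.0  # boundary 1
        x[70] = -5.0
        x[90] = 5.0  # boundary 2
        intervals = detect_stair_strides(x, FS)
        assert intervals == [(50, 90)]

    def test_single_boundary_no_strides(self):
        x = np.zeros(60)
        x[20] = -5.0
        x[40] = 5.0
        assert detect_stair_strides(x, FS) == []


class TestExtractMiddleStride:
    def _events(self, bounds):
        return GaitEvents([], [], {"left": bounds})

    def test_middle_of_five(self, walk_trial):
        bounds = [(i * 60, (i + 1) * 60) for i in range(5)]
        window = extract_middle_stride(walk_trial, self._events(bounds), "left")
        # stride index 2 spans samples 120..180
        filtered = lowpass_filter(walk_trial.angles["knee_flex_ext"], FS)
        assert window.normalized_angles["knee_flex_ext"][0] == pytest.approx(
            filtered[120]
        )

    def test_middle_of_four_tiebreaks_later(self, walk_trial):
        bounds = [(i * 60, (i + 1) * 60) for i in range(4)]
        window = extract_middle_stride(walk_trial, self._events(bounds), "left")
        filtered = lowpass_filter(walk_trial.angles["knee_flex_ext"], FS)
        assert window.normalized_angles["knee_flex_ext"][0] == pytest.approx(
            filtered[120]
        )

    def test_101_samples_every_channel(self, walk_trial):
        bounds = [(i * 55, (i + 1) * 55) for i in range(5)]
        window = extract_middle_stride(walk_trial, self._events(bounds), "left")
        for ch in ANGLE_CHANNELS:
            assert len(window.normalized_angles[ch]) == 101

    def test_endpoints_equal_filtered_boundary_values(self, walk_trial):
        bounds = [(i * 57, (i + 1) * 57) for i in range(5)]
        window = extract_middle_stride(walk_trial, self._events(bounds), "left")
        start, end = bounds[2]
        for ch in ANGLE_CHANNELS:
            filtered = lowpass_filter(walk_trial.angles[ch], FS)
            assert window.normalized_angles[ch][0] == pytest.approx(filtered[start])
            assert window.normalized_angles[ch][-1] == pytest.approx(filtered[end])

    def test_resampling_101_sample_stride_is_identity(self, walk_trial):
        # a stride already 101 samples long resamples to itself
        bounds = [(i * 100, i * 100 + 100) for i in range(3)]
        window = extract_middle_stride(walk_trial, self._events(bounds), "left")
        start, end = bounds[1]
        for ch in ANGLE_CHANNELS:
            filtered = lowpass_filter(walk_trial.angles[ch], FS)
            np.testing.assert_allclose(
                window.normalized_angles[ch], filtered[start : end + 1], atol=1e-9
            )

    def test_insufficient_strides_error_carries_context(self, walk_trial):
        with pytest.raises(InsufficientStridesError) as excinfo:
            extract_middle_stride(
                walk_trial, self._events([(0, 60), (60, 120)]), "left"
            )
        assert excinfo.value.subject_id == walk_trial.subject_id
        assert excinfo.value.activity == "walk"
        assert "insufficient strides" in str(excinfo.value)


class TestEventsAndSegmentation:
    def test_gait_events_validation(self):
        with pytest.raises(ValueError):
            GaitEvents([10, 5], ["left", "right"], {})
        with pytest.raises(ValueError):
            GaitEvents([5, 10], ["left", "right"], {"left": [(20, 10)]})

    def test_strides_from_steps(self):
        bounds = strides_from_steps(
            [10, 40, 70, 100, 130, 160],
            ["left", "right", "left", "right", "left", "right"],
        )
        assert bounds["left"] == [(10, 70), (70, 130)]
        assert bounds["right"] == [(40, 100), (100, 160)]

    def test_segment_trial_both_sides(self, walk_trial):
        windows = segment_trial(walk_trial)
        assert {w.side for w in windows} == {"left", "right"}
        for w in windows:
            assert w.n_points == 101

    def test_segment_stairs_trial(self, stairs_trial):
        windows = segment_trial(stairs_trial)
        assert {w.side for w in windows} == {"left", "right"}

    def test_detect_events_walking_matches_truth(self, walk_trial):
        events = detect_events(walk_trial)
        truth = walk_trial.true_events
        assert len(events.step_indices) == len(truth.step_indices)
        for d, t in zip(events.step_indices, truth.step_indices):
            assert abs(d - t) <= 2

    def test_normalize_points_configurable(self, walk_trial):
        windows = segment_trial(walk_trial, n_points=51)
        assert all(w.n_points == 51 for w in windows)


class TestSegmentationOracle:
    """Planted-truth recovery across seeds (scaled-down; full sweep in
    the acceptance suite)."""

    def test_walking_recovery_across_seeds(self):
        hits = total = 0
        for seed in range(3):
            trial = generate_trial(make_profile(), "walk", "w6", seed=seed)
            detected = detect_walking_steps(trial.accel_ap, FS)
            for t in trial.true_events.step_indices:
                total += 1
                hits += any(abs(d - t) <= 2 for d in detected)
        assert hits / total >= 0.95

    def test_stairs_recovery_across_seeds(self):
        hits = total = 0
        for seed in range(3):
            trial = generate_trial(make_profile(), "stairs_up", "w6", seed=seed)
            for side in ("left", "right"):
                detected = detect_stair_strides(trial.tibia_accel_x[side], FS)
                for ts, te in trial.true_events.stride_bounds[side]:
                    total += 1
                    hits += any(
                        abs(ds - ts) <= 2 and abs(de - te) <= 2
                        for ds, de in detected
                    )
        assert hits / total >= 0.95
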