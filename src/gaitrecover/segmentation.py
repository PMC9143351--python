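"""Gait event detection, middle-stride extraction and time normalization.

Walking steps come from peaks in the anterior-posterior acceleration, sides
from the sign of the medio-lateral acceleration around each step, and stair
strides from tibia-acceleration local maxima that follow a local minimum.
Joint angles are zero-phase low-pass filtered at 6 Hz and each selected
stride is resampled to 101 points (0..100% of stride time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from gaitrecover.synthetic_cohort import ANGLE_CHANNELS, SIDES, KinematicTrial

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_MIN_STEP_INTERVAL = 0.4  # seconds
DEFAULT_PROMINENCE_FACTOR = 0.5  # x signal standard deviation
DEFAULT_NORMALIZE_POINTS = 101
DEFAULT_SIDE_WINDOW = 0.2  # seconds


class InsufficientStridesError(ValueError):
    """Raised when fewer than 3 strides are available for a requested side."""

    def __init__(self, subject_id: str, activity: str, side: str, n_strides: int):
        self.subject_id = subject_id
        self.activity = activity
        self.side = side
        self.n_strides = n_strides
        super().__init__(
            f"insufficient strides for subject={subject_id} activity={activity} "
            f"side={side}: found {n_strides}, need >= 3"
        )


@dataclass
class GaitEvents:
    step_indices: list[int]
    step_sides: list[str]
    stride_bounds: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.step_indices, self.step_indices[1:])):
            raise ValueError("step indices must be strictly increasing")
        for side, bounds in self.stride_bounds.items():
            if any(end <= start for start, end in bounds):
                raise ValueError(f"stride end must exceed start (side={side})")


@dataclass
class StrideWindow:
    subject_id: str
    activity: str
    timepoint: str
    side: str
    normalized_angles: dict[str, np.ndarray]  # channel -> n_points samples

    @property
    def n_points(self) -> int:
        return len(next(iter(self.normalized_angles.values())))

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per % of stride, one column per channel."""
        df = pd.DataFrame({c: self.normalized_angles[c] for c in ANGLE_CHANNELS})
        df.index.name = "pct"
        return df


def lowpass_filter(
    series: np.ndarray,
    sample_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    Raises ``ValueError`` if the series is shorter than the filter warm-up
    length or the cutoff violates Nyquist.
    """
    series = np.asarray(series, dtype=float)
    if sample_rate <= 2.0 * cutoff:
        raise ValueError("sample_rate must exceed twice the cutoff frequency")
    b, a = butter(order, cutoff / (sample_rate / 2.0), btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(series) <= padlen:
        raise ValueError(
            f"series of length {len(series)} too short for zero-phase "
            f"filtering (needs > {padlen} samples)"
        )
    return filtfilt(b, a, series)


def detect_walking_steps(
    accel_ap: np.ndarray,
    sample_rate: float,
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> list[int]:
    """Step indices from peaks of the anterior-posterior acceleration.

    Peaks must exceed an adaptive prominence threshold
    (``prominence_factor * std``) and be separated by at least
    ``min_step_interval`` seconds; when two candidates are closer, the
    larger peak wins. An empty list is a valid result.
    """
    accel_ap = np.asarray(accel_ap, dtype=float)
    if accel_ap.size == 0:
        raise ValueError("accel_ap must be non-empty")
    sd = accel_ap.std()
    if sd == 0.0:
        return []
    distance = max(1, int(round(min_step_interval * sample_rate)))
    peaks, _ = find_peaks(accel_ap, prominence=prominence_factor * sd,
                          distance=distance)
    return [int(p) for p in peaks]


def assign_step_sides(
    step_indices: list[int],
    accel_ml: np.ndarray,
    sample_rate: float,
    window: float = DEFAULT_SIDE_WINDOW,
    positive_side: str = "left",
    default_side: str = "left",
) -> list[str]:
    """Side labels from the sign of the mean medio-lateral acceleration.

    The mean is taken over a window centred on each step (truncated at the
    series edges). A zero mean is a tie and falls back to ``default_side``.
    """
    accel_ml = np.asarray(accel_ml, dtype=float)
    n = accel_ml.size
    half = max(1, int(round(window * sample_rate / 2.0)))
    other = "right" if positive_side == "left" else "left"
    sides = []
    for idx in step_indices:
        if not 0 <= idx < n:
            raise ValueError(f"step index {idx} outside series of length {n}")
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        m = accel_ml[lo:hi].mean()
        if m > 0:
            sides.append(positive_side)
        elif m < 0:
            sides.append(other)
        else:
            logger.warning(
                "medio-lateral tie at step %d; defaulting to %s", idx, default_side
            )
            sides.append(default_side)
    return sides


def detect_stair_strides(
    tibia_accel_x: np.ndarray,
    sample_rate: float,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> list[tuple[int, int]]:
    """Stride intervals from tibia-acceleration extrema.

    A stride boundary is a local maximum that is the first local maximum
    after a preceding local minimum; consecutive boundaries delimit strides.
    Fewer than two boundaries yield an empty list.
    """
    x = np.asarray(tibia_accel_x, dtype=float)
    if x.size == 0:
        raise ValueError("tibia_accel_x must be non-empty")
    sd = x.std()
    if sd == 0.0:
        return []
    prominence = prominence_factor * sd
    maxima, _ = find_peaks(x, prominence=prominence)
    minima, _ = find_peaks(-x, prominence=prominence)
    extrema = sorted(
        [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    )
    boundaries = []
    prev_kind = None
    for idx, kind in extrema:
        if kind == "max" and prev_kind == "min":
            boundaries.append(idx)
        prev_kind = kind
    return list(zip(boundaries[:-1], boundaries[1:]))


def strides_from_steps(
    step_indices: list[int], step_sides: list[str]
) -> dict[str, list[tuple[int, int]]]:
    """Walking strides: consecutive same-side step events delimit one stride."""
    bounds: dict[str, list[tuple[int, int]]] = {side: [] for side in SIDES}
    last_seen: dict[str, int] = {}
    for idx, side in zip(step_indices, step_sides):
        if side in last_seen:
            bounds[side].append((last_seen[side], idx))
        last_seen[side] = idx
    return bounds


def detect_events(
    trial: KinematicTrial,
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    side_window: float = DEFAULT_SIDE_WINDOW,
) -> GaitEvents:
    """Detect gait events for a trial using the activity-appropriate channel."""
    if trial.activity == "walk":
        steps = detect_walking_steps(
            trial.accel_ap, trial.sample_rate, min_step_interval, prominence_factor
        )
        sides = assign_step_sides(steps, trial.accel_ml, trial.sample_rate,
                                  window=side_window)
        return GaitEvents(steps, sides, strides_from_steps(steps, sides))
    bounds = {
        side: detect_stair_strides(trial.tibia_accel_x[side], trial.sample_rate,
                                   prominence_factor)
        for side in SIDES
    }
    return GaitEvents([], [], bounds)


def extract_middle_stride(
    trial: KinematicTrial,
    events: GaitEvents,
    side: str,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    n_points: int = DEFAULT_NORMALIZE_POINTS,
) -> StrideWindow:
    """Select the middle stride for a side and time-normalize its angles.

    With ``n`` strides the stride at index ``floor(n / 2)`` (0-based) is
    selected; for even counts this is the later of the two central strides.
    All 9 angle channels are low-pass filtered over the full trial, sliced
    at the stride boundaries (inclusive), and linearly resampled to
    ``n_points`` samples on normalized time.
    """
    strides = events.stride_bounds.get(side, [])
    if len(strides) < 3:
        raise InsufficientStridesError(
            trial.subject_id, trial.activity, side, len(strides)
        )
    start, end = strides[len(strides) // 2]
    target = np.linspace(0.0, 1.0, n_points)
    normalized = {}
    for channel in ANGLE_CHANNELS:
        filtered = lowpass_filter(trial.angles[channel], trial.sample_rate, cutoff)
        segment = filtered[start : end + 1]
        source = np.linspace(0.0, 1.0, len(segment))
        normalized[channel] = np.interp(target, source, segment)
    return StrideWindow(
        subject_id=trial.subject_id,
        activity=trial.activity,
        timepoint=trial.timepoint,
        side=side,
        normalized_angles=normalized,
    )


def segment_trial(
    trial: KinematicTrial,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL,
    n_points: int = DEFAULT_NORMALIZE_POINTS,
    sides: tuple[str, ...] = SIDES,
) -> list[StrideWindow]:
    """Detect events and extract one middle stride per requested side.

    Sides with fewer than 3 detected strides are skipped with a warning
    rather than aborting the whole trial.
    """
    events = detect_events(trial, min_step_interval=min_step_interval)
    windows = []
    for side in sides:
        try:
            windows.append(
                extract_middle_stride(trial, events, side, cutoff, n_points)
            )
        except InsufficientStridesError as err:
            logger.warning("%s", err)
    return windows


def segment_cohort(
    trials: list[KinematicTrial],
    cutoff: float = DEFAULT_CUTOFF_HZ,
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL,
    n_points: int = DEFAULT_NORMALIZE_POINTS,
) -> list[StrideWindow]:
    windows: list[StrideWindow] = []
    for trial in trials:
        windows.extend(
            segment_trial(trial, cutoff, min_step_interval, n_points)
        )
    return windows
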