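"""Seeded synthetic gait cohorts: multichannel kinematic trials plus PROMs.

The generator produces the statistical structure the downstream analysis
assumes — periodic joint-angle channels whose deviation from a class-neutral
template scales with a latent severity, acceleration channels with planted
gait events, and a KOOS-ADL trajectory stochastically coupled to severity —
so that every stage can be tested without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

SAMPLE_RATE = 60.0

ANGLE_CHANNELS = (
    "spine_lat_bending",
    "spine_flex_ext",
    "spine_rotation",
    "hip_flex_ext",
    "hip_ab_adduction",
    "hip_int_ext_rotation",
    "knee_flex_ext",
    "knee_ab_adduction",
    "ankle_plantar_dorsiflexion",
)

ACTIVITIES = ("walk", "stairs_up", "stairs_down")

PATIENT_TIMEPOINTS = ("pre", "w6", "m3", "m6", "m12")
POSTOP_TIMEPOINTS = ("w6", "m3", "m6", "m12")
CONTROL_TIMEPOINT = "control_single"
TIMEPOINTS = PATIENT_TIMEPOINTS + (CONTROL_TIMEPOINT,)

SIDES = ("left", "right")

# Per-channel templates: (offset_deg, [(amplitude_deg, harmonic, phase_rad), ...]).
# Smooth sums of <= 4 harmonics of the stride frequency with magnitudes in the
# range typically reported for these joints; no claim of biomechanical fidelity.
_WALK_TEMPLATE = {
    "spine_lat_bending": (2.0, [(3.0, 2, 0.0), (1.0, 1, 0.7)]),
    "spine_flex_ext": (5.0, [(2.0, 2, 0.5), (0.8, 1, 0.0)]),
    "spine_rotation": (0.0, [(4.0, 1, 0.0), (1.0, 3, 1.1)]),
    "hip_flex_ext": (10.0, [(20.0, 1, 1.57), (4.0, 2, 0.8)]),
    "hip_ab_adduction": (2.0, [(5.0, 1, 1.0), (2.0, 2, 0.0)]),
    "hip_int_ext_rotation": (0.0, [(6.0, 1, 2.0), (1.5, 2, 0.4)]),
    "knee_flex_ext": (25.0, [(20.0, 1, 4.0), (12.0, 2, 1.2), (3.0, 3, 0.0)]),
    "knee_ab_adduction": (2.0, [(3.0, 1, 0.6), (1.0, 2, 2.2)]),
    "ankle_plantar_dorsiflexion": (0.0, [(10.0, 1, 2.5), (5.0, 2, 0.3)]),
}

# Amplitude/offset scalings applied on top of the walking template.
_STAIR_SCALE = {
    "stairs_up": {"amp": 1.3, "knee_offset": 15.0, "hip_offset": 8.0},
    "stairs_down": {"amp": 1.2, "knee_offset": 10.0, "hip_offset": 4.0},
}

# How a unit of effect_size * severity deforms each channel. Positive range
# coefficients shrink the oscillatory amplitude (stiffened joint); negative
# ones enlarge it (compensatory trunk motion). Offsets in degrees, phase in
# radians, asymmetry amplitudes in degrees at stride frequency.
_RANGE_COEF = {
    "spine_lat_bending": -0.15,
    "spine_flex_ext": -0.05,
    "spine_rotation": 0.05,
    "hip_flex_ext": 0.15,
    "hip_ab_adduction": 0.10,
    "hip_int_ext_rotation": 0.08,
    "knee_flex_ext": 0.25,
    "knee_ab_adduction": 0.10,
    "ankle_plantar_dorsiflexion": 0.12,
}
_OFFSET_COEF = {
    "spine_lat_bending": 1.5,
    "spine_flex_ext": 1.2,
    "spine_rotation": 0.3,
    "hip_flex_ext": 1.0,
    "hip_ab_adduction": 0.4,
    "hip_int_ext_rotation": 0.3,
    "knee_flex_ext": -2.0,
    "knee_ab_adduction": 0.5,
    "ankle_plantar_dorsiflexion": 0.3,
}
_PHASE_COEF = {
    "knee_flex_ext": 0.25,
    "ankle_plantar_dorsiflexion": 0.15,
    "hip_flex_ext": 0.10,
}
_ASYM_COEF = {
    "knee_flex_ext": 1.5,
    "hip_flex_ext": 1.0,
    "spine_lat_bending": 0.8,
}

# Phase offset of the first planted left step, in strides; keeps the first
# event peak away from the series boundary.
_START_PHASE = 0.3


@dataclass
class TrueEvents:
    """Ground-truth event annotations planted by the generator.

    Oracle tests compare detector output against these; they are never
    serialized, so file-based runs exercise detection only.
    """

    step_indices: list[int]
    step_sides: list[str]
    stride_bounds: dict[str, list[tuple[int, int]]]


@dataclass
class SubjectProfile:
    subject_id: str
    group: str  # "control" | "patient"
    affected_side: str  # "left" | "right" | "none"
    latent_severity: dict[str, float]  # timepoint -> [0, 1]
    cadence_hz: float  # steps per second
    dropout_after: Optional[str] = None
    stairs_capable: dict[str, bool] = field(default_factory=dict)

    @property
    def timepoints(self) -> tuple[str, ...]:
        """Evaluation moments at which this subject contributes trials."""
        if self.group == "control":
            return (CONTROL_TIMEPOINT,)
        tps = PATIENT_TIMEPOINTS
        if self.dropout_after is not None:
            cut = PATIENT_TIMEPOINTS.index(self.dropout_after)
            tps = PATIENT_TIMEPOINTS[: cut + 1]
        return tps


@dataclass
class KinematicTrial:
    subject_id: str
    activity: str
    timepoint: str
    side: str  # affected side label ("none" for controls)
    sample_rate: float
    angles: dict[str, np.ndarray]  # 9 channels, degrees
    accel_ap: np.ndarray  # anterior-posterior pelvis acceleration, m/s^2
    accel_ml: np.ndarray  # medio-lateral pelvis acceleration, m/s^2
    tibia_accel_x: dict[str, np.ndarray]  # per-leg longitudinal tibia accel
    true_events: Optional[TrueEvents] = None

    @property
    def n_samples(self) -> int:
        return len(self.accel_ap)


@dataclass
class PROMTrajectory:
    subject_id: str
    koos_adl: dict[str, float]  # timepoint -> [0, 100]


@dataclass
class CohortDataset:
    profiles: list[SubjectProfile]
    trials: list[KinematicTrial]
    proms: list[PROMTrajectory]
    seed: int
    params: dict = field(default_factory=dict)

    def profile_map(self) -> dict[str, SubjectProfile]:
        return {p.subject_id: p for p in self.profiles}


def template_series(activity: str, channel: str, phase: np.ndarray) -> np.ndarray:
    """Class-neutral periodic template evaluated at stride phase (in strides)."""
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity: {activity!r}")
    offset, harmonics = _WALK_TEMPLATE[channel]
    amp_scale = 1.0
    if activity in _STAIR_SCALE:
        scale = _STAIR_SCALE[activity]
        amp_scale = scale["amp"]
        if channel == "knee_flex_ext":
            offset = offset + scale["knee_offset"]
        elif channel == "hip_flex_ext":
            offset = offset + scale["hip_offset"]
    out = np.full_like(phase, offset, dtype=float)
    for amp, k, ph in harmonics:
        out += amp_scale * amp * np.sin(2.0 * np.pi * k * phase + ph)
    return out


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float,
                  sample_rate: float, band_hz: float = 4.0) -> np.ndarray:
    """White Gaussian noise band-limited below the 6 Hz kinematic filter."""
    if sigma == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.normal(0.0, sigma, n)
    if n < 30:  # too short for filtfilt padding; leave white
        return white
    b, a = butter(2, band_hz / (sample_rate / 2.0), btype="low")
    smooth = filtfilt(b, a, white)
    sd = smooth.std()
    if sd > 0:
        smooth *= sigma / sd
    return smooth


def _gaussian_bump(n: int, center: float, width: float) -> np.ndarray:
    idx = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((idx - center) / width) ** 2)


def generate_trial(
    profile: SubjectProfile,
    activity: str,
    timepoint: str,
    n_cycles: int = 8,
    seed: int = 0,
    *,
    effect_size: float = 1.0,
    noise_scale: float = 1.0,
    sample_rate: float = SAMPLE_RATE,
) -> KinematicTrial:
    """Generate one recorded repetition for a subject.

    Angle channels are a periodic per-activity template plus severity-scaled
    deviations (amplitude reduction, offset shift, timing shift, left-right
    asymmetry) plus smooth sub-6 Hz noise. Acceleration channels carry one
    dominant peak per step (AP), alternating-sign deflections per side (ML),
    and one local-min-then-local-max pattern per stride boundary on each
    leg's tibia series, with ground truth recorded in ``true_events``.

    Exactly ``2 * n_cycles`` steps are planted (n_cycles per side), giving
    ``n_cycles - 1`` strides per leg.
    """
    if timepoint not in profile.latent_severity:
        raise ValueError(
            f"profile {profile.subject_id} has no timepoint {timepoint!r}"
        )
    if n_cycles < 5:
        raise ValueError("n_cycles must be >= 5 so a middle stride exists")
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity: {activity!r}")

    severity = float(profile.latent_severity[timepoint])
    es = effect_size * severity

    cadence = profile.cadence_hz
    if activity != "walk":
        cadence = cadence * 0.75  # stairs are negotiated more slowly
    stride_dur = 2.0 / cadence  # seconds per stride (two steps per stride)
    stride_samples = stride_dur * sample_rate
    n = int(round((n_cycles + 2.0 * _START_PHASE) * stride_samples))
    t = np.arange(n) / sample_rate
    phase = t / stride_dur  # in strides; left steps at phase = _START_PHASE + k

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # --- planted events -------------------------------------------------
    left_phases = _START_PHASE + np.arange(n_cycles)
    right_phases = left_phases + 0.5
    left_idx = np.round(left_phases * stride_samples).astype(int)
    right_idx = np.round(right_phases * stride_samples).astype(int)
    left_idx = left_idx[left_idx < n]
    right_idx = right_idx[right_idx < n]

    steps = sorted(
        [(int(i), "left") for i in left_idx] + [(int(i), "right") for i in right_idx]
    )
    step_indices = [i for i, _ in steps]
    step_sides = [s for _, s in steps]
    stride_bounds = {
        "left": list(zip(left_idx[:-1].tolist(), left_idx[1:].tolist())),
        "right": list(zip(right_idx[:-1].tolist(), right_idx[1:].tolist())),
    }
    events = TrueEvents(step_indices, step_sides, stride_bounds)

    # --- joint angles ---------------------------------------------------
    asym_sign = -1.0 if profile.affected_side == "right" else 1.0
    stride_phase = phase - _START_PHASE
    angles: dict[str, np.ndarray] = {}
    for channel in ANGLE_CHANNELS:
        offset, harmonics = _WALK_TEMPLATE[channel]
        amp_scale = 1.0
        if activity in _STAIR_SCALE:
            sc = _STAIR_SCALE[activity]
            amp_scale = sc["amp"]
            if channel == "knee_flex_ext":
                offset = offset + sc["knee_offset"]
            elif channel == "hip_flex_ext":
                offset = offset + sc["hip_offset"]
        amp_factor = max(1.0 - _RANGE_COEF[channel] * es, 0.05)
        phase_shift = _PHASE_COEF.get(channel, 0.0) * es
        series = np.full(n, offset + _OFFSET_COEF[channel] * es)
        for amp, k, ph in harmonics:
            series += (
                amp_scale
                * amp
                * amp_factor
                * np.sin(2.0 * np.pi * k * stride_phase + ph + phase_shift)
            )
        asym = _ASYM_COEF.get(channel, 0.0)
        if asym and es > 0:
            series += asym_sign * asym * es * np.sin(2.0 * np.pi * stride_phase)
        series += _smooth_noise(rng, n, 1.0 * noise_scale, sample_rate)
        angles[channel] = series

    # --- accelerations --------------------------------------------------
    accel_ap = _smooth_noise(rng, n, 0.12 * noise_scale, sample_rate)
    accel_ap += 0.3 * np.sin(2.0 * np.pi * stride_phase)
    for i in step_indices:
        amp = 3.0 * (1.0 + 0.1 * rng.normal())
        accel_ap += amp * _gaussian_bump(n, i, 2.0)

    accel_ml = _smooth_noise(rng, n, 0.15 * noise_scale, sample_rate)
    for i, s in zip(step_indices, step_sides):
        sgn = 1.0 if s == "left" else -1.0
        accel_ml += sgn * 1.5 * _gaussian_bump(n, i, 3.0)

    tibia: dict[str, np.ndarray] = {}
    boundaries = {"left": left_idx, "right": right_idx}
    for leg in SIDES:
        # noise kept well below the adaptive prominence threshold so the
        # planted min-then-max pattern is the only qualifying extrema pair
        series = _smooth_noise(rng, n, 0.05 * noise_scale, sample_rate)
        for b in boundaries[leg]:
            series += -2.5 * _gaussian_bump(n, b - 4, 1.5)
            series += 3.0 * _gaussian_bump(n, b, 1.5)
        tibia[leg] = series

    return KinematicTrial(
        subject_id=profile.subject_id,
        activity=activity,
        timepoint=timepoint,
        side=profile.affected_side,
        sample_rate=sample_rate,
        angles=angles,
        accel_ap=accel_ap,
        accel_ml=accel_ml,
        tibia_accel_x=tibia,
        true_events=events,
    )


def _patient_severity(rng: np.random.Generator, recovering: bool) -> dict[str, float]:
    sev_pre = rng.uniform(0.75, 0.95)
    sev_w6 = rng.uniform(0.6, 0.9)
    if not recovering:
        return {tp: sev_w6 for tp in PATIENT_TIMEPOINTS} | {"pre": sev_pre}
    sev_m12 = rng.uniform(0.05, 0.35)
    total = sev_w6 - sev_m12
    fracs = rng.uniform(0.5, 1.5, 3)
    fracs = fracs / fracs.sum()
    sev_m3 = sev_w6 - fracs[0] * total
    sev_m6 = sev_m3 - fracs[1] * total
    return {"pre": sev_pre, "w6": sev_w6, "m3": sev_m3, "m6": sev_m6, "m12": sev_m12}


def generate_cohort(
    n_controls: int,
    n_patients: int,
    effect_size: float,
    coupling: float,
    seed: int,
    *,
    stairs_incapable_frac: float = 1.0 / 3.0,
    activities: tuple[str, ...] = ACTIVITIES,
    n_cycles: int = 8,
    trials_per_cell: int = 1,
    noise_scale: float = 1.0,
    dropouts: bool = True,
    nonrecovering_frac: float = 0.0,
    koos_base: float = 70.0,
    koos_noise_sd: float = 15.0,
) -> CohortDataset:
    """Generate a full seeded cohort: profiles, trials and PROM trajectories.

    Controls receive one evaluation; patients receive trials at pre, 6 weeks,
    3, 6 and 12 months, subject to dropout and stairs-capability flags.
    ``effect_size`` scales how strongly latent severity deforms the gait
    signals (0 = patient and control signals exchangeable); ``coupling``
    in [0, 1] controls how deterministically KOOS-ADL follows severity
    (1 = koos is exactly 100 * (1 - severity)).

    The same arguments and seed yield a bitwise-identical dataset.
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("n_controls and n_patients must both be >= 2")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    for act in activities:
        if act not in ACTIVITIES:
            raise ValueError(f"unknown activity: {act!r}")

    ss = np.random.SeedSequence(seed)
    ss_profiles, ss_trials, ss_proms = ss.spawn(3)
    rng = np.random.default_rng(ss_profiles)

    profiles: list[SubjectProfile] = []
    for i in range(n_controls):
        profiles.append(
            SubjectProfile(
                subject_id=f"ctrl{i + 1:02d}",
                group="control",
                affected_side="none",
                latent_severity={CONTROL_TIMEPOINT: 0.0},
                # cadence is deliberately group-independent: with
                # effect_size = 0 the two groups must be exchangeable
                cadence_hz=rng.uniform(1.5, 2.0),
                stairs_capable={CONTROL_TIMEPOINT: True},
            )
        )

    n_nonrec = int(round(nonrecovering_frac * n_patients))
    nonrec_ids = set(rng.permutation(n_patients)[:n_nonrec].tolist())
    n_incapable = int(round(stairs_incapable_frac * n_patients))
    incapable_ids = set(rng.permutation(n_patients)[:n_incapable].tolist())
    if dropouts and n_patients >= 4:
        drop_pair = rng.permutation(n_patients)[:2]
        dropout_map = {int(drop_pair[0]): "pre", int(drop_pair[1]): "m6"}
    else:
        dropout_map = {}

    for i in range(n_patients):
        severity = _patient_severity(rng, recovering=i not in nonrec_ids)
        stairs_capable = {tp: True for tp in PATIENT_TIMEPOINTS}
        if i in incapable_ids:
            stairs_capable["w6"] = False
        profiles.append(
            SubjectProfile(
                subject_id=f"pat{i + 1:02d}",
                group="patient",
                affected_side="left" if rng.random() < 0.5 else "right",
                latent_severity=severity,
                # same cadence law as controls (see comment above)
                cadence_hz=rng.uniform(1.5, 2.0),
                dropout_after=dropout_map.get(i),
                stairs_capable=stairs_capable,
            )
        )

    trials: list[KinematicTrial] = []
    trial_rng = np.random.default_rng(ss_trials)
    for profile in profiles:
        for timepoint in profile.timepoints:
            for activity in activities:
                if activity != "walk" and not profile.stairs_capable.get(
                    timepoint, True
                ):
                    continue
                for _ in range(trials_per_cell):
                    trial_seed = int(trial_rng.integers(0, 2**31 - 1))
                    trials.append(
                        generate_trial(
                            profile,
                            activity,
                            timepoint,
                            n_cycles=n_cycles,
                            seed=trial_seed,
                            effect_size=effect_size,
                            noise_scale=noise_scale,
                        )
                    )

    prom_rng = np.random.default_rng(ss_proms)
    proms: list[PROMTrajectory] = []
    for profile in profiles:
        koos: dict[str, float] = {}
        for timepoint in profile.timepoints:
            sev = profile.latent_severity[timepoint]
            deterministic = 100.0 * (1.0 - sev)
            noisy = koos_base + prom_rng.normal(0.0, koos_noise_sd)
            value = coupling * deterministic + (1.0 - coupling) * noisy
            koos[timepoint] = float(np.clip(value, 0.0, 100.0))
        proms.append(PROMTrajectory(subject_id=profile.subject_id, koos_adl=koos))

    params = {
        "n_controls": n_controls,
        "n_patients": n_patients,
        "effect_size": effect_size,
        "coupling": coupling,
        "seed": seed,
        "stairs_incapable_frac": stairs_incapable_frac,
        "activities": list(activities),
        "n_cycles": n_cycles,
        "trials_per_cell": trials_per_cell,
        "noise_scale": noise_scale,
        "dropouts": dropouts,
        "nonrecovering_frac": nonrecovering_frac,
        "koos_base": koos_base,
        "koos_noise_sd": koos_noise_sd,
    }
    return CohortDataset(profiles=profiles, trials=trials, proms=proms,
                         seed=seed, params=params)


def mean_template_deviation(trial: KinematicTrial, cadence_hz: float) -> float:
    """Mean absolute deviation of a trial's angle channels from the neutral template.

    Used as a scalar gait-deviation summary in monotonicity checks.
    """
    cadence = cadence_hz if trial.activity == "walk" else cadence_hz * 0.75
    stride_dur = 2.0 / cadence
    n = trial.n_samples
    phase = (np.arange(n) / trial.sample_rate) / stride_dur - _START_PHASE
    total = 0.0
    for channel in ANGLE_CHANNELS:
        ref = template_series(trial.activity, channel, phase)
        total += float(np.mean(np.abs(trial.angles[channel] - ref)))
    return total / len(ANGLE_CHANNELS)
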