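"""Scalar feature construction via series fusion and a fixed statistical bank.

Each stride contributes a set of views: the 9 input angle channels plus
fused series built by binary operators (ratio, difference, sum, product)
over pairs of input channels. Redundant candidates — those whose absolute
Pearson correlation with any already-retained view reaches the threshold
(default 0.99) — are pruned. The candidate set is determined once on
training data (on the concatenated training series) and reused verbatim for
evaluation data. From every retained view a fixed bank of 15 statistics is
extracted, and features are averaged per subject per activity per
timepoint: both legs for controls, affected side only for patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gaitrecover.segmentation import StrideWindow
from gaitrecover.synthetic_cohort import ANGLE_CHANNELS, SubjectProfile

logger = logging.getLogger(__name__)

FUSION_OPERATIONS = ("ratio", "difference", "sum", "product")
RATIO_EPS_REL = 1e-6  # x channel RMS; denominators closer to zero are guarded

FEATURE_BANK_VERSION = "1"
FEATURE_NAMES = (
    "mean",
    "variance",
    "min",
    "max",
    "median",
    "range",
    "rms",
    "fft_mag_1",
    "fft_mag_2",
    "fft_mag_3",
    "fft_mag_4",
    "fft_mag_5",
    "trend_slope",
    "trend_intercept",
    "trend_r",
)


@dataclass(frozen=True)
class ViewSpec:
    """Recipe for a view: an input channel or a binary fusion of two inputs."""

    name: str
    operation: Optional[str] = None  # None for input channels
    operands: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"name": self.name, "operation": self.operation,
                "operands": list(self.operands)}

    @classmethod
    def from_dict(cls, d: dict) -> "ViewSpec":
        return cls(d["name"], d["operation"], tuple(d["operands"]))


@dataclass
class View:
    name: str
    series: np.ndarray
    provenance: str  # "input" | "fused"
    spec: ViewSpec = None

    def __post_init__(self) -> None:
        if self.spec is None:
            self.spec = ViewSpec(self.name)


@dataclass
class FusionConfig:
    corr_threshold: float = 0.99
    operations: tuple[str, ...] = FUSION_OPERATIONS
    max_generated: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        for op in self.operations:
            if op not in FUSION_OPERATIONS:
                raise ValueError(f"unknown fusion operation: {op!r}")

    def to_dict(self) -> dict:
        return {
            "corr_threshold": self.corr_threshold,
            "operations": list(self.operations),
            "max_generated": self.max_generated,
        }


@dataclass
class FeatureMatrix:
    """Per subject-activity-timepoint rows of named scalar features."""

    values: pd.DataFrame  # MultiIndex (subject_id, activity, timepoint)
    view_specs: list[ViewSpec]
    config: FusionConfig = field(default_factory=FusionConfig)
    provenance: Optional[pd.DataFrame] = None  # sides used, n strides averaged

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.values.index.get_level_values("subject_id")))

    def subset(self, subjects: Sequence[str]) -> "FeatureMatrix":
        mask = self.values.index.get_level_values("subject_id").isin(set(subjects))
        prov = self.provenance[mask] if self.provenance is not None else None
        return FeatureMatrix(self.values[mask], self.view_specs, self.config, prov)

    def to_csv(self, path, sidecar_path=None) -> None:
        self.values.to_csv(path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "feature_bank_version": FEATURE_BANK_VERSION,
                        "config": self.config.to_dict(),
                        "view_specs": [s.to_dict() for s in self.view_specs],
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def read_csv(cls, path, sidecar_path) -> "FeatureMatrix":
        values = pd.read_csv(path, index_col=["subject_id", "activity", "timepoint"])
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        cfg = FusionConfig(
            corr_threshold=meta["config"]["corr_threshold"],
            operations=tuple(meta["config"]["operations"]),
            max_generated=meta["config"]["max_generated"],
        )
        specs = [ViewSpec.from_dict(d) for d in meta["view_specs"]]
        return cls(values, specs, cfg)


def _apply_operation(op: str, a: np.ndarray, b: np.ndarray,
                     guard_ratio: bool = False) -> Optional[np.ndarray]:
    if op == "sum":
        return a + b
    if op == "difference":
        return a - b
    if op == "product":
        return a * b
    if op == "ratio":
        rms = float(np.sqrt(np.mean(b**2)))
        eps = RATIO_EPS_REL * rms
        if rms == 0.0 or (not guard_ratio and np.min(np.abs(b)) < eps):
            return None
        if guard_ratio:
            b = np.sign(b) * np.maximum(np.abs(b), eps)
            b[b == 0] = eps
        return a / b
    raise ValueError(f"unknown fusion operation: {op!r}")


def _candidate_specs(names: Sequence[str],
                     operations: Sequence[str]) -> list[ViewSpec]:
    """Deterministic enumeration of fusion candidates over input-view pairs."""
    specs = []
    for op in operations:
        pairs = (
            permutations(names, 2) if op == "ratio" else combinations(names, 2)
        )
        for a, b in pairs:
            specs.append(ViewSpec(f"{op}({a},{b})", op, (a, b)))
    return specs


def fuse_views(inputs: list[View], config: FusionConfig) -> list[View]:
    """Generate fused views and prune correlation-redundant candidates.

    A candidate is retained only if its absolute Pearson correlation with
    every already-retained view (inputs first, then earlier candidates) is
    below ``corr_threshold``; a threshold of 1.0 disables the filter.
    Ratio candidates whose denominator passes near zero are skipped.
    """
    lengths = {len(v.series) for v in inputs}
    if len(lengths) > 1:
        raise ValueError(f"input views have mismatched lengths: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0

    def standardize(x: np.ndarray) -> Optional[np.ndarray]:
        x = x - x.mean()
        sd = np.sqrt(np.mean(x**2))
        if sd == 0.0:
            return None
        return x / sd

    retained = list(inputs)
    by_name = {v.name: v.series for v in inputs}
    z_rows = [standardize(v.series) for v in retained]
    z = np.array([r if r is not None else np.zeros(n) for r in z_rows])

    vacuous = config.corr_threshold >= 1.0
    generated = 0
    for spec in _candidate_specs([v.name for v in inputs], config.operations):
        if generated >= config.max_generated:
            break
        a, b = by_name[spec.operands[0]], by_name[spec.operands[1]]
        series = _apply_operation(spec.operation, a, b)
        if series is None:
            logger.info("skipping %s: denominator passes near zero", spec.name)
            continue
        if not np.all(np.isfinite(series)):
            logger.info("skipping %s: non-finite values", spec.name)
            continue
        zc = standardize(series)
        if zc is None:
            logger.info("skipping %s: constant series", spec.name)
            continue
        if not vacuous:
            corr = np.abs(z @ zc) / n
            if corr.max() >= config.corr_threshold:
                continue
        retained.append(View(spec.name, series, "fused", spec))
        z = np.vstack([z, zc])
        generated += 1
    return retained


def extract_features(view) -> dict[str, float]:
    """Fixed 15-feature bank for one view.

    Simple statistics (mean, variance, min, max, median, range, RMS),
    magnitudes of discrete Fourier coefficients 1-5 of the mean-subtracted
    series, and linear-trend statistics (slope, intercept, Pearson r) of
    value against normalized time in [0, 1]. Variance is the population
    variance; the trend r of a constant series is defined as 0.
    """
    series = np.asarray(view.series if isinstance(view, View) else view,
                        dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    n = len(series)
    mean = float(series.mean())
    centered = series - mean
    fft_mags = np.abs(np.fft.rfft(centered))
    fft_mags = np.pad(fft_mags, (0, max(0, 6 - len(fft_mags))))[1:6]

    t = np.linspace(0.0, 1.0, n)
    t_c = t - t.mean()
    var_t = float(np.mean(t_c**2))
    cov = float(np.mean(t_c * centered))
    slope = cov / var_t
    intercept = mean - slope * float(t.mean())
    sd_y = float(np.sqrt(np.mean(centered**2)))
    r = cov / (np.sqrt(var_t) * sd_y) if sd_y > 0 else 0.0

    out = {
        "mean": mean,
        "variance": float(np.mean(centered**2)),
        "min": float(series.min()),
        "max": float(series.max()),
        "median": float(np.median(series)),
        "range": float(series.max() - series.min()),
        "rms": float(np.sqrt(np.mean(series**2))),
        "trend_slope": float(slope),
        "trend_intercept": float(intercept),
        "trend_r": float(r),
    }
    for k in range(5):
        out[f"fft_mag_{k + 1}"] = float(fft_mags[k])
    return {name: out[name] for name in FEATURE_NAMES}


def _stride_sort_key(s: StrideWindow):
    return (s.subject_id, s.activity, s.timepoint, s.side)


def determine_view_specs(strides: list[StrideWindow],
                         config: FusionConfig) -> list[ViewSpec]:
    """Fix the view list from training strides.

    Correlation pruning is computed on the per-channel series concatenated
    over all training strides (in deterministic stride order), so retention
    is a property of the training dataset, not of any single trial.
    """
    ordered = sorted(strides, key=_stride_sort_key)
    inputs = [
        View(
            channel,
            np.concatenate([s.normalized_angles[channel] for s in ordered]),
            "input",
        )
        for channel in ANGLE_CHANNELS
    ]
    return [v.spec for v in fuse_views(inputs, config)]


def materialize_views(stride: StrideWindow,
                      specs: list[ViewSpec]) -> list[View]:
    """Compute the series for each view spec on a single stride.

    Ratio denominators are clamped away from zero at materialization time so
    a view retained on training data never yields non-finite values on
    unseen data.
    """
    channels = stride.normalized_angles
    views = []
    for spec in specs:
        if spec.operation is None:
            series = np.asarray(channels[spec.name], dtype=float)
            views.append(View(spec.name, series, "input", spec))
        else:
            a = np.asarray(channels[spec.operands[0]], dtype=float)
            b = np.asarray(channels[spec.operands[1]], dtype=float)
            series = _apply_operation(spec.operation, a, b, guard_ratio=True)
            views.append(View(spec.name, series, "fused", spec))
    return views


def stride_feature_vector(stride: StrideWindow,
                          specs: list[ViewSpec]) -> dict[str, float]:
    """Flat ``view__feature`` -> value map for one stride.

    Results are memoised per (stride, view spec): under leave-one-subject-out
    evaluation the same stride is re-featurised in every fold, usually with a
    largely identical view list.
    """
    cache = getattr(stride, "_feature_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(stride, "_feature_cache", cache)
    data: dict[str, float] = {}
    missing = [s for s in specs if s not in cache]
    if missing:
        for view in materialize_views(stride, missing):
            cache[view.spec] = extract_features(view)
    for spec in specs:
        for fname, value in cache[spec].items():
            data[f"{spec.name}__{fname}"] = value
    return data


def build_feature_matrix(
    strides: list[StrideWindow],
    profiles: list[SubjectProfile] | dict[str, SubjectProfile],
    config: Optional[FusionConfig] = None,
    view_specs: Optional[list[ViewSpec]] = None,
) -> FeatureMatrix:
    """Fuse, extract and aggregate features into one row per
    (subject, activity, timepoint).

    For controls both legs' strides are averaged; for patients only the
    affected side contributes — strides from the unaffected side are
    excluded with a warning. When ``view_specs`` is None the fusion
    candidate set is determined from the given strides (training usage);
    passing persisted specs reproduces the training-time view list exactly
    (evaluation usage).
    """
    if config is None:
        config = FusionConfig()
    if isinstance(profiles, dict):
        profile_map = profiles
    else:
        profile_map = {p.subject_id: p for p in profiles}

    kept: list[StrideWindow] = []
    for stride in strides:
        if stride.subject_id not in profile_map:
            raise ValueError(f"stride subject {stride.subject_id!r} not in profiles")
        profile = profile_map[stride.subject_id]
        if profile.group == "patient" and stride.side != profile.affected_side:
            logger.warning(
                "excluding unaffected-side stride: subject=%s side=%s",
                stride.subject_id, stride.side,
            )
            continue
        kept.append(stride)

    if view_specs is None:
        view_specs = determine_view_specs(kept, config)

    groups: dict[tuple[str, str, str], list[StrideWindow]] = {}
    for stride in sorted(kept, key=_stride_sort_key):
        groups.setdefault(
            (stride.subject_id, stride.activity, stride.timepoint), []
        ).append(stride)

    rows, index, prov = [], [], []
    for key, members in sorted(groups.items()):
        vectors = [stride_feature_vector(s, view_specs) for s in members]
        columns = list(vectors[0])
        stacked = np.array([[v[c] for c in columns] for v in vectors])
        rows.append(pd.Series(stacked.mean(axis=0), index=columns))
        index.append(key)
        prov.append(
            {"sides": ",".join(sorted({s.side for s in members})),
             "n_strides": len(members)}
        )
    idx = pd.MultiIndex.from_tuples(
        index, names=["subject_id", "activity", "timepoint"]
    )
    values = pd.DataFrame(rows, index=idx)
    provenance = pd.DataFrame(prov, index=idx)
    return FeatureMatrix(values, list(view_specs), config, provenance)
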