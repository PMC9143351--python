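"""Longitudinal deployment of trained models and correlation with PROMs.

A trained model is applied to post-operative timepoints to build one
probability trajectory per patient; missing trials stay gaps (no
imputation). Trajectories are related to KOOS-ADL functioning via a group
Spearman correlation on 6-week-to-12-month change scores and per-subject
longitudinal Spearman correlations banded weak/fair/moderate/strong at
|rho| cut-points 0.25 / 0.5 / 0.75.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from gaitrecover.classifier import TrainedModel, predict_probability
from gaitrecover.feature_construction import FeatureMatrix
from gaitrecover.synthetic_cohort import PROMTrajectory, POSTOP_TIMEPOINTS

logger = logging.getLogger(__name__)

PRE_TRAINED = "pre_trained"
W6_TRAINED = "w6_trained"

DEPLOYMENT_TIMEPOINTS = {
    PRE_TRAINED: ("w6", "m3", "m6", "m12"),
    W6_TRAINED: ("m3", "m6", "m12"),
}

BANDS = ("weak", "fair", "moderate", "strong")


def band_of(rho: float) -> str:
    """Band of |rho|: weak [0,0.25), fair [0.25,0.5), moderate [0.5,0.75),
    strong [0.75,1]."""
    a = abs(rho)
    if math.isnan(a) or a > 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if a < 0.25:
        return "weak"
    if a < 0.5:
        return "fair"
    if a < 0.75:
        return "moderate"
    return "strong"


@dataclass
class RecoveryTrajectory:
    subject_id: str
    activity: str
    p_tka: dict[str, float]  # timepoint -> probability; absent = gap
    model_variant: str


@dataclass
class ChangeScores:
    """Per-subject 6-week-to-12-month differences; both endpoints required."""

    delta_p: dict[str, float]
    delta_koos: dict[str, float]
    excluded: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.delta_p) & set(self.delta_koos))


@dataclass
class IndividualCorrelation:
    rho: Optional[float]
    p_value: Optional[float]
    n_points: int
    band: Optional[str]
    flag: Optional[str] = None  # "insufficient" | "undefined"


@dataclass
class CorrelationReport:
    group_rho: float
    group_p: float
    n_group: int
    individual: dict[str, IndividualCorrelation]

    def band_fractions(self) -> dict[str, float]:
        banded = [c.band for c in self.individual.values() if c.band is not None]
        if not banded:
            return {b: float("nan") for b in BANDS}
        return {b: banded.count(b) / len(banded) for b in BANDS}


def deploy_over_time(
    model: TrainedModel,
    features: FeatureMatrix,
    variant: str,
) -> list[RecoveryTrajectory]:
    """Score every patient row at the variant's deployment timepoints.

    Rows must carry the model's persisted feature columns (built with its
    view list); feature-set mismatches raise. Timepoints with no trial are
    simply absent from the trajectory.
    """
    if variant not in DEPLOYMENT_TIMEPOINTS:
        raise ValueError(f"unknown model variant: {variant!r}")
    deploy_tps = DEPLOYMENT_TIMEPOINTS[variant]
    tp_level = features.values.index.get_level_values("timepoint")
    rows = features.values[tp_level.isin(deploy_tps)]
    if rows.empty:
        return []
    scores = predict_probability(model, rows)
    by_subject: dict[tuple[str, str], dict[str, float]] = {}
    for s in scores:
        by_subject.setdefault((s.subject_id, s.activity), {})[s.timepoint] = s.p_tka
    return [
        RecoveryTrajectory(subject_id, activity, p_map, variant)
        for (subject_id, activity), p_map in sorted(by_subject.items())
    ]


def _koos_map(proms: list[PROMTrajectory]) -> dict[str, dict[str, float]]:
    return {p.subject_id: p.koos_adl for p in proms}


def compute_change_scores(
    trajs: list[RecoveryTrajectory],
    proms: list[PROMTrajectory],
    baseline_w6: Optional[dict[str, float]] = None,
) -> ChangeScores:
    """Delta p = p(m12) - p(w6) and Delta KOOS = koos(m12) - koos(w6).

    ``baseline_w6`` supplies p(w6) for trajectories that do not contain it
    (the 6-week-trained variant, where w6 is training data and held-out
    LOOCV scores are the honest choice). Subjects missing either endpoint
    are excluded and listed.
    """
    koos = _koos_map(proms)
    delta_p: dict[str, float] = {}
    delta_koos: dict[str, float] = {}
    excluded: list[str] = []
    for traj in trajs:
        sid = traj.subject_id
        p_w6 = traj.p_tka.get("w6")
        if p_w6 is None and baseline_w6 is not None:
            p_w6 = baseline_w6.get(sid)
        p_m12 = traj.p_tka.get("m12")
        k = koos.get(sid, {})
        if p_w6 is None or p_m12 is None or "w6" not in k or "m12" not in k:
            excluded.append(sid)
            continue
        delta_p[sid] = p_m12 - p_w6
        delta_koos[sid] = k["m12"] - k["w6"]
    return ChangeScores(delta_p, delta_koos, excluded)


def group_correlation(changes: ChangeScores) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with two-sided p on change scores."""
    subjects = changes.subjects
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subject change-score pairs, got {len(subjects)}")
    dp = [changes.delta_p[s] for s in subjects]
    dk = [changes.delta_koos[s] for s in subjects]
    result = stats.spearmanr(dp, dk)
    return float(result.statistic), float(result.pvalue)


def individual_correlations(
    trajs: list[RecoveryTrajectory],
    proms: list[PROMTrajectory],
    baseline_w6: Optional[dict[str, float]] = None,
) -> dict[str, IndividualCorrelation]:
    """Per-subject Spearman rho of p_tka against KOOS-ADL over post-op points.

    Uses the shared timepoints among (w6, m3, m6, m12); subjects with fewer
    than 3 are flagged "insufficient" and zero rank variance (e.g. constant
    KOOS) is flagged "undefined" — neither receives a band. With 4 points
    the rho support is coarse and p-values are unreliable; they are
    reported anyway and should be read with that caveat.
    """
    koos = _koos_map(proms)
    out: dict[str, IndividualCorrelation] = {}
    for traj in trajs:
        sid = traj.subject_id
        p_map = dict(traj.p_tka)
        if "w6" not in p_map and baseline_w6 is not None and sid in baseline_w6:
            p_map["w6"] = baseline_w6[sid]
        k = koos.get(sid, {})
        tps = [tp for tp in POSTOP_TIMEPOINTS if tp in p_map and tp in k]
        if len(tps) < 3:
            out[sid] = IndividualCorrelation(None, None, len(tps), None,
                                             flag="insufficient")
            continue
        p_vals = [p_map[tp] for tp in tps]
        k_vals = [k[tp] for tp in tps]
        if len(set(p_vals)) == 1 or len(set(k_vals)) == 1:
            out[sid] = IndividualCorrelation(None, None, len(tps), None,
                                             flag="undefined")
            continue
        result = stats.spearmanr(p_vals, k_vals)
        rho = float(result.statistic)
        out[sid] = IndividualCorrelation(rho, float(result.pvalue), len(tps),
                                         band_of(rho))
    return out


def build_correlation_report(
    trajs: list[RecoveryTrajectory],
    proms: list[PROMTrajectory],
    baseline_w6: Optional[dict[str, float]] = None,
) -> CorrelationReport:
    changes = compute_change_scores(trajs, proms, baseline_w6)
    rho, p = group_correlation(changes)
    individual = individual_correlations(trajs, proms, baseline_w6)
    return CorrelationReport(rho, p, len(changes.subjects), individual)


def export_heatmap_table(
    trajs: list[RecoveryTrajectory],
    timepoints: tuple[str, ...] = POSTOP_TIMEPOINTS,
) -> pd.DataFrame:
    """Subjects x timepoints matrix of p_tka; NaN marks a gap (no trial).

    Subjects are ordered by id so the table is deterministic; written as
    CSV the gaps render as empty cells.
    """
    subjects = sorted({t.subject_id for t in trajs})
    data = {
        tp: [
            next(
                (t.p_tka.get(tp, np.nan) for t in trajs if t.subject_id == sid),
                np.nan,
            )
            for sid in subjects
        ]
        for tp in timepoints
    }
    df = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    return df


def plot_heatmap(table: pd.DataFrame, path) -> None:
    """Thin optional plotting layer: probability heatmap with gaps left blank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(table))))
    im = ax.imshow(table.to_numpy(), cmap="Greys", vmin=0.0, vmax=1.0,
                   aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns)
    ax.set_yticks(range(table.shape[0]), table.index)
    fig.colorbar(im, ax=ax, label="p(TKA class)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(
    trajs: list[RecoveryTrajectory],
    proms: list[PROMTrajectory],
    path,
    baseline_w6: Optional[dict[str, float]] = None,
) -> None:
    """Per-subject probability and KOOS-ADL curves over post-op timepoints."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    koos = _koos_map(proms)
    n = max(1, len(trajs))
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False)
    for ax, traj in zip(axes.flat, sorted(trajs, key=lambda t: t.subject_id)):
        p_map = dict(traj.p_tka)
        if "w6" not in p_map and baseline_w6 and traj.subject_id in baseline_w6:
            p_map["w6"] = baseline_w6[traj.subject_id]
        tps = [tp for tp in POSTOP_TIMEPOINTS if tp in p_map]
        ax.plot(tps, [p_map[tp] for tp in tps], "o-", label="p(TKA)")
        ax.set_ylim(0, 1)
        k = koos.get(traj.subject_id, {})
        ktps = [tp for tp in POSTOP_TIMEPOINTS if tp in k]
        twin = ax.twinx()
        twin.plot(ktps, [k[tp] for tp in ktps], "s--", color="tab:orange",
                  label="KOOS-ADL")
        twin.set_ylim(0, 100)
        ax.set_title(traj.subject_id, fontsize=8)
    for ax in axes.flat[len(trajs):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
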