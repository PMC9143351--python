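"""L1-regularised logistic regression with nested tuning and per-subject CV.

Features are standard-scaled with statistics computed from training rows
only; the regularisation parameter is tuned over 10 log-spaced values in
[0.01, 1] by 5-fold stratified CV on mean AUC; the final model is fit with
the LIBLINEAR solver capped at 100 iterations. Evaluation is
leave-one-subject-out: every row of the held-out subject is excluded from
scaling, view determination (when a refit builder is supplied) and tuning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from gaitrecover.feature_construction import FeatureMatrix, ViewSpec

logger = logging.getLogger(__name__)

CONTROL_CLASS = "control"
TKA_CLASS = "tka"


def default_c_grid() -> np.ndarray:
    """Ten regularisation values scaled logarithmically between 0.01 and 1."""
    return np.logspace(-2.0, 0.0, 10)


@dataclass
class ScalerParams:
    columns: list[str]
    mean: np.ndarray
    std: np.ndarray
    zero_variance_mask: np.ndarray  # True where the column is dropped

    @property
    def retained_columns(self) -> list[str]:
        return [c for c, m in zip(self.columns, self.zero_variance_mask) if not m]


@dataclass
class ModelSpec:
    c_grid: np.ndarray = field(default_factory=default_c_grid)
    inner_folds: int = 5
    max_iterations: int = 100
    decision_boundary: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.c_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("C grid must be strictly increasing")
        self.c_grid = grid


@dataclass
class TrainedModel:
    scaler: ScalerParams
    weights: pd.Series  # over the scaler's retained columns
    intercept: float
    chosen_C: float
    inner_cv_auc: dict[float, float]  # C -> mean AUC over inner folds
    spec: ModelSpec
    view_specs: Optional[list[ViewSpec]] = None
    converged: bool = True

    def nonzero_weights(self) -> pd.Series:
        return self.weights[self.weights != 0.0]


@dataclass
class ProbabilityScore:
    subject_id: str
    activity: str
    timepoint: str
    p_tka: float
    predicted_class: str


def _as_frame(data) -> pd.DataFrame:
    return data.values if isinstance(data, FeatureMatrix) else data


def fit_scaler(train) -> ScalerParams:
    """Per-column mean and population std from training rows only.

    Zero-variance columns are masked out of the modelled feature set.
    """
    df = _as_frame(train)
    if len(df) < 2:
        raise ValueError("need >= 2 training rows to fit a scaler")
    mean = df.mean(axis=0).to_numpy()
    std = df.std(axis=0, ddof=0).to_numpy()
    mask = std == 0.0
    if mask.any():
        dropped = [c for c, m in zip(df.columns, mask) if m]
        logger.info("masking %d zero-variance columns: %s",
                    len(dropped), dropped[:5])
    return ScalerParams(list(df.columns), mean, std, mask)


def apply_scaler(params: ScalerParams, rows) -> pd.DataFrame:
    """(x - train_mean) / train_std per retained column.

    Evaluation rows are never re-centred on themselves; only training-set
    statistics are used.
    """
    df = _as_frame(rows)
    missing = [c for c in params.retained_columns if c not in df.columns]
    if missing:
        raise ValueError(f"rows are missing model columns: {missing[:5]}")
    keep = ~params.zero_variance_mask
    cols = params.retained_columns
    x = df[cols].to_numpy(dtype=float)
    scaled = (x - params.mean[keep]) / params.std[keep]
    return pd.DataFrame(scaled, index=df.index, columns=cols)


def _encode_labels(labels, index: pd.MultiIndex) -> np.ndarray:
    """Labels may be keyed by subject_id or aligned to the row index."""
    if isinstance(labels, pd.Series):
        if labels.index.nlevels == 1 and labels.index.name in (None, "subject_id"):
            subject_ids = index.get_level_values("subject_id")
            values = labels.reindex(subject_ids).to_numpy()
        else:
            values = labels.reindex(index).to_numpy()
    else:
        values = np.asarray(labels)
    encoded = np.where(np.asarray(values) == TKA_CLASS, 1, 0)
    if pd.isna(values).any():
        raise ValueError("labels missing for some rows")
    return encoded


def _fit_l1(x: np.ndarray, y: np.ndarray, c: float, spec: ModelSpec):
    # l1_ratio=1.0 is the L1 penalty under sklearn >= 1.8's parametrisation
    model = LogisticRegression(
        l1_ratio=1.0,
        C=float(c),
        solver="liblinear",
        max_iter=spec.max_iterations,
        random_state=spec.seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(x, y)
        except ConvergenceWarning:
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x, y)
            converged = False
            logger.warning(
                "liblinear did not converge within %d iterations (C=%g); "
                "keeping current iterate", spec.max_iterations, c,
            )
    return model, converged


def tune_and_train(train, labels, spec: Optional[ModelSpec] = None) -> TrainedModel:
    """Tune C by stratified inner CV on mean AUC, then fit on all rows.

    Ties in mean AUC resolve toward the smaller C (stronger
    regularisation). The scaler is refit inside each inner fold so tuning
    sees no statistics from its validation split.
    """
    if spec is None:
        spec = ModelSpec()
    df = _as_frame(train)
    y = _encode_labels(labels, df.index)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < spec.inner_folds:
        raise ValueError(
            f"minority class has {counts.min()} rows; "
            f"need >= {spec.inner_folds} for stratified inner CV"
        )

    skf = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                          random_state=spec.seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    # Scale each inner fold once (training-split statistics only), then sweep C.
    fold_data = []
    for train_idx, val_idx in splits:
        scaler = fit_scaler(df.iloc[train_idx])
        x_tr = apply_scaler(scaler, df.iloc[train_idx]).to_numpy()
        x_va = apply_scaler(scaler, df.iloc[val_idx]).to_numpy()
        fold_data.append((x_tr, y[train_idx], x_va, y[val_idx]))

    cv_table: dict[float, float] = {}
    for c in spec.c_grid:
        aucs = []
        for x_tr, y_tr, x_va, y_va in fold_data:
            model, _ = _fit_l1(x_tr, y_tr, c, spec)
            aucs.append(roc_auc_score(y_va, model.decision_function(x_va)))
        cv_table[float(c)] = float(np.mean(aucs))

    aucs = np.array([cv_table[float(c)] for c in spec.c_grid])
    best_c = float(spec.c_grid[int(np.argmax(aucs))])  # first max = smaller C

    scaler = fit_scaler(df)
    x = apply_scaler(scaler, df).to_numpy()
    model, converged = _fit_l1(x, y, best_c, spec)
    weights = pd.Series(model.coef_[0], index=scaler.retained_columns)
    view_specs = train.view_specs if isinstance(train, FeatureMatrix) else None
    return TrainedModel(
        scaler=scaler,
        weights=weights,
        intercept=float(model.intercept_[0]),
        chosen_C=best_c,
        inner_cv_auc=cv_table,
        spec=spec,
        view_specs=view_specs,
        converged=converged,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_probability(model: TrainedModel, rows) -> list[ProbabilityScore]:
    """p_tka = 1 / (1 + exp(-(w . x_scaled + b))); class tka iff p > boundary.

    A probability exactly at the boundary is classified as control.
    """
    df = _as_frame(rows)
    if isinstance(df, pd.Series):
        df = df.to_frame().T
    scaled = apply_scaler(model.scaler, df)
    z = scaled.to_numpy() @ model.weights.to_numpy() + model.intercept
    probs = _sigmoid(z)
    scores = []
    for (subject_id, activity, timepoint), p in zip(df.index, probs):
        cls = TKA_CLASS if p > model.spec.decision_boundary else CONTROL_CLASS
        scores.append(
            ProbabilityScore(subject_id, activity, timepoint, float(p), cls)
        )
    return scores


RefitBuilder = Callable[[Sequence[str], Sequence[str]],
                        tuple[FeatureMatrix, FeatureMatrix]]


def loocv_evaluate(
    data: FeatureMatrix,
    labels: pd.Series,
    spec: Optional[ModelSpec] = None,
    refit: Optional[RefitBuilder] = None,
) -> tuple[list[ProbabilityScore], float]:
    """Leave-one-subject-out evaluation of the full pipeline.

    Each fold holds out every row of one subject; the scaler and tuning run
    on the remaining subjects only. When ``refit`` is given it rebuilds the
    training and held-out feature matrices from scratch for each fold
    (including fusion-view determination), so no dataset-level statistic
    leaks from the held-out subject. Accuracy is correct/total at the
    decision boundary.
    """
    if spec is None:
        spec = ModelSpec()
    subjects = data.subjects
    label_by_subject = labels if isinstance(labels, pd.Series) else pd.Series(labels)

    class_of = {s: label_by_subject.loc[s] for s in subjects}
    for cls in (CONTROL_CLASS, TKA_CLASS):
        if sum(1 for s in subjects if class_of[s] == cls) < 3:
            raise ValueError(f"need >= 3 subjects per class (class {cls!r})")

    all_scores: list[ProbabilityScore] = []
    correct = 0
    total = 0
    for held_out in subjects:
        train_subjects = [s for s in subjects if s != held_out]
        if len({class_of[s] for s in train_subjects}) < 2:
            raise ValueError(
                f"fold holding out {held_out!r} leaves a single-class remainder"
            )
        if refit is not None:
            train_fm, test_fm = refit(train_subjects, [held_out])
        else:
            train_fm, test_fm = data.subset(train_subjects), data.subset([held_out])
        model = tune_and_train(train_fm, label_by_subject, spec)
        scores = predict_probability(model, test_fm)
        for score in scores:
            total += 1
            if score.predicted_class == class_of[held_out]:
                correct += 1
        all_scores.extend(scores)
    return all_scores, correct / total
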