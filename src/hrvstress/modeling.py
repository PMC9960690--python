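"""Imbalanced-learning classification stage.

Per training fold, in order: 1.5×IQR outlier-row removal, SMOTE minority
oversampling to class balance, robust (median/IQR) scaling, then a
ridge-penalised logistic regression or a random forest.  Every statistic
(outlier bounds, SMOTE neighbours, scaler median/IQR) is computed from
training rows only; test rows are transformed with the stored training
statistics.

SMOTE is implemented here directly: each synthetic minority sample is
``x + u * (x_nn - x)`` for a random minority row ``x``, one of its k nearest
minority neighbours ``x_nn`` (Euclidean), and ``u ~ Uniform(0, 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import NearestNeighbors

from hrvstress.data_io import (
    META_COLUMNS,
    NON_STRESS,
    STRESS,
    PipelineConfig,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("hrvstress")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind plus hyperparameters.

    The random-forest defaults are the tuned configuration: entropy split
    criterion, sqrt features per split, depth cap 6, min 2 samples to split,
    200 trees (min_samples_leaf left at the conventional default 1).  The
    logistic regression is ridge-penalised at default strength with an
    iteration cap of 1000 and tolerance 1e-4.
    """

    kind: str = "RF"
    criterion: str = "entropy"
    max_features: str = "sqrt"
    max_depth: int | None = 6
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    n_estimators: int = 200
    C: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LR", "RF"):
            raise ValidationError(f"model kind must be 'LR' or 'RF', got {self.kind!r}")

    def build(self):
        if self.kind == "RF":
            return RandomForestClassifier(
                criterion=self.criterion,
                max_features=self.max_features,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                n_estimators=self.n_estimators,
                random_state=self.seed,
            )
        # sklearn's default penalty is the ridge (l2) this stage wants
        return LogisticRegression(
            C=self.C, max_iter=self.max_iter, tol=self.tol, random_state=self.seed,
        )


def default_rf_spec(seed: int = 0) -> ModelSpec:
    return ModelSpec(kind="RF", seed=seed)


def default_lr_spec(seed: int = 0) -> ModelSpec:
    return ModelSpec(kind="LR", seed=seed)


@dataclass
class FitState:
    """Everything learned from a training fold, for audit and reuse.

    All statistics are computed from training rows only; ``transform`` applies
    them unchanged to held-out data.
    """

    feature_names: list
    outlier_bounds: pd.DataFrame      # per-feature lower/upper rows
    scaler_median: pd.Series
    scaler_iqr: pd.Series             # zero-IQR features stored with divisor 1
    model: object
    spec: ModelSpec
    positive_label: str = STRESS

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise SchemaError(f"apply table missing feature column(s): {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        return (X - self.scaler_median.to_numpy()) / self.scaler_iqr.to_numpy()

    def predict(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Hard labels (1 = stress) and continuous scores for a feature table."""
        X = self.transform(table)
        pos = list(self.model.classes_).index(1)
        score = self.model.predict_proba(X)[:, pos]
        return self.model.predict(X), score


def feature_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLUMNS]


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map condition labels to the internal 1 = stress / 0 = non-stress coding."""
    arr = np.asarray(labels)
    out = np.empty(arr.shape, dtype=int)
    for i, v in enumerate(arr.ravel()):
        if v in (STRESS, 1, "1"):
            out.ravel()[i] = 1
        elif v in (NON_STRESS, 0, "0"):
            out.ravel()[i] = 0
        else:
            raise ValidationError(f"label {v!r} not in {{stress, non_stress}}")
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def iqr_outlier_filter(
    table: pd.DataFrame, columns: list | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove rows with any feature strictly outside its 1.5×IQR bounds.

    Per feature, bounds are ``(Q1 - 1.5*IQR, Q3 + 1.5*IQR)`` with type-7
    quantiles; a row is dropped iff any feature value lies strictly outside.
    Returns the filtered table and the per-feature bounds for audit.  A
    constant column has collapsed bounds but removes nothing (boundary values
    are inside).
    """
    if len(table) < 4:
        raise ValidationError("IQR outlier filter needs at least 4 rows")
    columns = columns or feature_columns(table)
    X = table[columns].to_numpy(dtype=float)
    q1 = np.quantile(X, 0.25, axis=0)
    q3 = np.quantile(X, 0.75, axis=0)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = ((X >= lower) & (X <= upper)).all(axis=1)
    removed = int((~keep).sum())
    if removed > 0.5 * len(table):
        logger.warning(
            "IQR filter removed %d of %d rows (>50%%) — proceeding", removed, len(table)
        )
    bounds = pd.DataFrame({"lower": lower, "upper": upper}, index=columns)
    return table.loc[keep].reset_index(drop=True), bounds


def smote_upsample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Grow the minority class to the majority count with SMOTE.

    Each synthetic row interpolates a minority row toward one of its ``k``
    nearest minority neighbours with a Uniform(0,1) factor, so every
    synthetic point lies on a segment between two real minority points.
    Deterministic under a fixed seed.  ``k`` is clipped to minority-1 with a
    warning when necessary; a singleton minority raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"SMOTE needs exactly 2 classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    if n_min == 1:
        raise ValidationError("SMOTE cannot oversample a singleton minority class")
    if k >= n_min:
        logger.warning("SMOTE k=%d >= minority count %d; clipping to %d", k, n_min, n_min - 1)
        k = n_min - 1

    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(n_new)
    Xs = Xm[base] + u[:, None] * (Xm[neigh[base, pick]] - Xm[base])
    return np.vstack([X, Xs]), np.concatenate([y, np.full(n_new, minority)])


def robust_scale(
    fit_on: pd.DataFrame, apply_to: pd.DataFrame | None = None,
    columns: list | None = None,
) -> tuple[np.ndarray, pd.Series, pd.Series]:
    """Center by the training median and scale by the training IQR.

    Returns the scaled values of ``apply_to`` (default: the fit table itself)
    plus the median and IQR series.  Zero-IQR features use divisor 1 with a
    warning.
    """
    if fit_on.empty:
        raise ValidationError("cannot fit scaler on an empty table")
    columns = columns or feature_columns(fit_on)
    apply_to = fit_on if apply_to is None else apply_to
    missing = [c for c in columns if c not in apply_to.columns]
    if missing:
        raise SchemaError(f"apply table missing feature column(s): {missing}")
    X = fit_on[columns].to_numpy(dtype=float)
    median = np.median(X, axis=0)
    iqr = np.quantile(X, 0.75, axis=0) - np.quantile(X, 0.25, axis=0)
    if np.any(iqr == 0):
        logger.warning("zero-IQR feature(s) during scaling; divisor set to 1")
        iqr = np.where(iqr == 0, 1.0, iqr)
    scaled = (apply_to[columns].to_numpy(dtype=float) - median) / iqr
    return scaled, pd.Series(median, index=columns), pd.Series(iqr, index=columns)


def train_classifier(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit the classifier of ``spec``; single-class training data raises."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValidationError("training data contains a single class")
    model = spec.build()
    model.fit(np.asarray(X, dtype=float), y)
    return model


# ---------------------------------------------------------------------------
# fold pipeline
# ---------------------------------------------------------------------------

def fit_pipeline(
    train: pd.DataFrame, spec: ModelSpec, config: PipelineConfig | None = None
) -> FitState:
    """Fit the full leakage-safe stage chain on one training table.

    Order: IQR outlier removal (training rows only, unless the config opts
    out), SMOTE to balance, robust scaling, classifier fit.  The returned
    :class:`FitState` carries every training statistic for audit.
    """
    config = config or PipelineConfig()
    cols = feature_columns(train)
    if config.outlier_scope == "train":
        train, bounds = iqr_outlier_filter(train, cols)
    else:  # table assumed pre-filtered by the caller ("all" scope)
        bounds = pd.DataFrame(
            {"lower": -np.inf, "upper": np.inf}, index=cols
        )
    y = encode_labels(train["label"])
    X = train[cols].to_numpy(dtype=float)
    Xb, yb = smote_upsample(X, y, k=config.smote_k, seed=config.seed)
    bal = pd.DataFrame(Xb, columns=cols)
    Xs, median, iqr = robust_scale(bal, columns=cols)
    model = train_classifier(spec, Xs, yb)
    return FitState(
        feature_names=cols,
        outlier_bounds=bounds,
        scaler_median=median,
        scaler_iqr=iqr,
        model=model,
        spec=spec,
    )


def predict_pipeline(state: FitState, test: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted pipeline to held-out rows: (hard labels, scores)."""
    if test.empty:
        raise ValidationError("empty test table")
    return state.predict(test)


def grid_search(
    grid: Sequence[ModelSpec],
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    n_folds: int = 10,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Pick the spec maximising mean cross-validated score AUC.

    Folds are grouped by subject so no subject straddles train and test; the
    fold count is reduced (with a warning) when there are fewer subjects than
    folds.  Ties break toward the first spec in the given deterministic
    order.  Returns the winner and the per-spec score log.
    """
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    config = config or PipelineConfig()
    groups = table["subject_id"].to_numpy()
    n_subjects = np.unique(groups).size
    if n_folds > n_subjects:
        logger.warning("n_folds=%d > %d subjects; reducing", n_folds, n_subjects)
        n_folds = n_subjects
    splitter = GroupKFold(n_splits=n_folds)
    y_all = encode_labels(table["label"])

    rows = []
    best_spec, best_score = None, -np.inf
    for spec_idx, spec in enumerate(grid):
        fold_scores = []
        for train_idx, test_idx in splitter.split(table, y_all, groups):
            train, test = table.iloc[train_idx], table.iloc[test_idx]
            y_test = y_all[test_idx]
            if np.unique(y_test).size < 2:
                continue  # AUC undefined on a single-class fold
            state = fit_pipeline(train, spec, config)
            _, score = state.predict(test)
            fold_scores.append(roc_auc_score(y_test, score))
        mean_auc = float(np.mean(fold_scores)) if fold_scores else 0.0
        rows.append((spec_idx, spec.kind, mean_auc, len(fold_scores)))
        if mean_auc > best_score:
            best_spec, best_score = spec, mean_auc
    log = pd.DataFrame(rows, columns=["spec_index", "kind", "mean_auc", "n_folds_scored"])
    return best_spec, log
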