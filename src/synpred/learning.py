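"""Model construction: AUC criterion, stratified 10-fold CV, sequential
backward feature selection, and seeded random-forest training with grid
search over (ntree, mtry).

The cross-validation driver re-fits zero-imputation and z-score
normalisation inside every training fold, scores the held-out fold with the
frozen parameters, and computes a single AUC on the pooled out-of-fold
scores — the criterion used both by the feature-selection wrapper and the
grid search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .feature_matrix import FeatureMatrix, impute_missing, zscore_apply, zscore_fit

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters: forest size, per-split candidate
    features (mtry), and the RNG seed."""

    ntree: int = 500
    mtry: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1 or self.mtry < 1:
            raise ValueError("ntree and mtry must be positive")


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to score new variants."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    config: RFConfig
    norm_params: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the deleterious class for each row of ``X``.

        Columns are reordered to training order; extra columns are ignored
        with a warning; missing required columns are an error.
        """
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing required feature columns: {missing}")
        extra = [c for c in X.columns if c not in self.feature_names]
        if extra:
            warnings.warn(f"ignoring extra feature columns: {extra}")
        X = X[self.feature_names]
        proba = self.estimator.predict_proba(X.to_numpy())
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


@dataclass
class SelectionTrace:
    """Accepted removal steps of the backward-selection wrapper."""

    steps: list[tuple[str, float]]  # (removed feature, criterion after removal)
    final_subset: list[str]
    final_criterion: float
    initial_criterion: float

    @property
    def removed(self) -> list[str]:
        return [name for name, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["removed_feature", "criterion"])


def auc(labels, scores) -> float:
    """Area under the ROC curve (rank-based; ties credited 0.5).

    Equals the probability that a random positive outranks a random negative.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = set(np.unique(labels))
    if classes != {0, 1}:
        raise ValueError(f"need both classes (0 and 1) present, got {classes}")
    return float(roc_auc_score(labels, scores))


def _as_xy(matrix, labels):
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        if labels is None:
            labels = matrix.labels
    else:
        X = pd.DataFrame(matrix)
    if labels is None:
        raise ValueError("labels are required")
    y = pd.Series(np.asarray(labels, dtype=int), index=X.index)
    return X, y


def _fit_forest(X: np.ndarray, y: np.ndarray, config: RFConfig) -> RandomForestClassifier:
    mtry = min(config.mtry, X.shape[1])
    clf = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=mtry,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def kfold_cv_auc(
    matrix,
    labels=None,
    rf_config: RFConfig = RFConfig(),
    k: int = 10,
    fold_seed: int = 0,
    feature_subset: list[str] | None = None,
) -> float:
    """Stratified k-fold CV criterion: AUC of pooled out-of-fold scores.

    Imputation and z-scoring are fitted on each training fold only.
    """
    X, y = _as_xy(matrix, labels)
    if feature_subset is not None:
        X = X[feature_subset]
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < k:
        raise ValueError(f"each class must have at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        fm_train = FeatureMatrix(X.iloc[train_idx], X.iloc[train_idx].isna())
        fm_test = FeatureMatrix(X.iloc[test_idx], X.iloc[test_idx].isna())
        params = zscore_fit(impute_missing(fm_train))
        Xtr = zscore_apply(impute_missing(fm_train), params).values
        Xte = zscore_apply(impute_missing(fm_test), params).values
        clf = _fit_forest(Xtr.to_numpy(), y.iloc[train_idx].to_numpy(), rf_config)
        pos_col = list(clf.classes_).index(1)
        oof[test_idx] = clf.predict_proba(Xte.to_numpy())[:, pos_col]
    return auc(y.to_numpy(), oof)


def sbs_select(
    matrix,
    labels=None,
    rf_config: RFConfig = RFConfig(),
    k: int = 10,
    fold_seed: int = 0,
    strict: bool = False,
) -> SelectionTrace:
    """Sequential backward selection with the CV-AUC criterion.

    Greedy loop: evaluate the criterion with each single feature removed and
    accept the removal yielding the highest criterion, provided it does not
    fall below the current criterion (``strict=True`` demands a strict
    improvement).  Ties between equally good removals drop the
    lexicographically smallest feature name.  Stops when every removal
    degrades the criterion, or one feature remains.
    """
    X, y = _as_xy(matrix, labels)
    current = list(X.columns)
    if len(current) < 2:
        crit = kfold_cv_auc(X, y, rf_config, k, fold_seed)
        return SelectionTrace([], current, crit, crit)
    criterion = kfold_cv_auc(X, y, rf_config, k, fold_seed, feature_subset=current)
    initial = criterion
    steps: list[tuple[str, float]] = []
    while len(current) > 1:
        candidates = []
        for name in current:
            subset = [f for f in current if f != name]
            crit = kfold_cv_auc(X, y, rf_config, k, fold_seed, feature_subset=subset)
            candidates.append((crit, name))
        # best removal: highest criterion; ties -> smallest feature name
        best_crit = max(c for c, _ in candidates)
        best_name = min(n for c, n in candidates if c == best_crit)
        accept = best_crit > criterion if strict else best_crit >= criterion
        if not accept:
            break
        current = [f for f in current if f != best_name]
        criterion = best_crit
        steps.append((best_name, best_crit))
        logger.info("sbs: removed %s -> criterion %.4f", best_name, best_crit)
    return SelectionTrace(steps, current, criterion, initial)


def grid_search(
    matrix,
    labels=None,
    ntree_grid: list[int] | None = None,
    mtry_grid: list[int] | None = None,
    k: int = 10,
    fold_seed: int = 0,
    rf_seed: int = 0,
) -> tuple[RFConfig, pd.DataFrame]:
    """Evaluate the CV criterion at every (ntree, mtry) grid point.

    The default grid is ntree in {50, 100, ..., 1000} x mtry in {1, ..., 10}
    (200 points).  The best configuration maximises the criterion; ties are
    broken by smaller ntree, then smaller mtry.  Grid points with mtry
    exceeding the feature count are skipped with a warning.
    """
    X, y = _as_xy(matrix, labels)
    if ntree_grid is None:
        ntree_grid = list(range(50, 1001, 50))
    if mtry_grid is None:
        mtry_grid = list(range(1, 11))
    rows = []
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            if mtry > X.shape[1]:
                warnings.warn(
                    f"skipping grid point mtry={mtry} > {X.shape[1]} features"
                )
                continue
            config = RFConfig(ntree=ntree, mtry=mtry, seed=rf_seed)
            crit = kfold_cv_auc(X, y, config, k, fold_seed)
            rows.append({"ntree": ntree, "mtry": mtry, "criterion": crit})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("grid search evaluated no configurations")
    best_row = table.sort_values(
        ["criterion", "ntree", "mtry"], ascending=[False, True, True]
    ).iloc[0]
    best = RFConfig(ntree=int(best_row.ntree), mtry=int(best_row.mtry), seed=rf_seed)
    return best, table


def train_rf(
    matrix,
    labels=None,
    rf_config: RFConfig = RFConfig(),
    norm_params: pd.DataFrame | None = None,
) -> TrainedModel:
    """Fit a seeded random forest on an (already normalised) feature matrix."""
    X, y = _as_xy(matrix, labels)
    classes = set(y.unique())
    if classes != {0, 1}:
        raise ValueError(f"labels must contain both classes, got {classes}")
    if rf_config.mtry > X.shape[1]:
        raise ValueError(
            f"mtry={rf_config.mtry} exceeds {X.shape[1]} available features"
        )
    clf = _fit_forest(X.to_numpy(), y.to_numpy(), rf_config)
    if norm_params is None and isinstance(matrix, FeatureMatrix):
        norm_params = matrix.norm_params
    return TrainedModel(
        estimator=clf,
        feature_names=list(X.columns),
        config=rf_config,
        norm_params=norm_params,
    )


def predict(model: TrainedModel, matrix) -> np.ndarray:
    """Per-variant deleteriousness probability for new rows."""
    X = matrix.values if isinstance(matrix, FeatureMatrix) else pd.DataFrame(matrix)
    return model.predict_proba(X)


def save_model(model: TrainedModel, path: str) -> None:
    """Persist a trained model as a single-file bundle with metadata."""
    bundle = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "feature_names": model.feature_names,
        "config": asdict(model.config),
        "norm_params": model.norm_params,
        "metadata": model.metadata,
    }
    joblib.dump(bundle, path)


def load_model(path: str) -> TrainedModel:
    try:
        bundle = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ValueError(f"{path} is not a model bundle")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {bundle['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    return TrainedModel(
        estimator=bundle["estimator"],
        feature_names=bundle["feature_names"],
        config=RFConfig(**bundle["config"]),
        norm_params=bundle["norm_params"],
        metadata=bundle.get("metadata", {}),
    )
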