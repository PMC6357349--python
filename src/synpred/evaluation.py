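"""Imbalance-aware evaluation: confusion counts, recall/precision, the
β-weighted F-measure, gene-matched negative filtering, balanced-subset
resampling with a paired t-test, leave-one-feature-out ablation, and a
class-imbalance sweep.

The F-measure weight β is set to the (rounded) majority/minority class
ratio of the test set, so that on heavily imbalanced data the score is
dominated by recall — F_β → recall as β → ∞, and β = 1 recovers the usual
harmonic mean of precision and recall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import learning
from .genomic_io import Variant
from .learning import RFConfig, kfold_cv_auc

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Confusion counts plus recall, precision, F_β and AUC for one run."""

    TP: int
    FP: int
    TN: int
    FN: int
    recall: float
    precision: float
    f_measure: float
    auc: float
    beta: float

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def to_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "beta": self.beta,
        }


def confusion(labels, probs, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with probability >= threshold predicting deleterious."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    pred = probs >= threshold
    TP = int(np.sum(pred & (labels == 1)))
    FP = int(np.sum(pred & (labels == 0)))
    TN = int(np.sum(~pred & (labels == 0)))
    FN = int(np.sum(~pred & (labels == 1)))
    return TP, FP, TN, FN


def f_beta(recall: float, precision: float, beta: float) -> float:
    """Weighted F-measure ((β²+1)·P·R) / (β²·P + R); 0 when both are zero."""
    if recall == 0 and precision == 0:
        return 0.0
    b2 = beta * beta
    return ((b2 + 1) * precision * recall) / (b2 * precision + recall)


def class_ratio_beta(n_neg: int, n_pos: int) -> int:
    """β as the majority/minority class ratio, rounded to nearest integer."""
    if n_pos == 0:
        raise ValueError("no positive examples")
    return int(round(max(n_neg, n_pos) / min(n_neg, n_pos)))


def evaluate(labels, probs, beta: float = 1.0, threshold: float = 0.5) -> EvalResult:
    """Bundle confusion counts, recall, precision, F_β and AUC for one run."""
    TP, FP, TN, FN = confusion(labels, probs, threshold)
    recall = TP / (TP + FN) if TP + FN else 0.0
    precision = TP / (TP + FP) if TP + FP else 0.0
    return EvalResult(
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        recall=recall,
        precision=precision,
        f_measure=f_beta(recall, precision, beta),
        auc=learning.auc(labels, probs),
        beta=beta,
    )


def gene_matched_negative_filter(
    negatives: list[Variant],
    positives: list[Variant],
    gene_of: dict[str, str],
    training: list[Variant] | None = None,
) -> list[Variant]:
    """Keep putative negatives from genes that host at least one positive.

    Avoids comparing classes drawn from different genomic neighbourhoods.
    Negatives without a gene assignment are dropped with a warning, as are
    negatives identical to any supplied training variant.
    """
    positive_genes = {gene_of[v.id] for v in positives if v.id in gene_of}
    training_ids = {v.id for v in training} if training else set()
    kept = []
    for v in negatives:
        gene = gene_of.get(v.id)
        if gene is None:
            warnings.warn(f"negative {v.id} has no gene assignment; dropped")
            continue
        if v.id in training_ids:
            continue
        if gene in positive_genes:
            kept.append(v)
    return kept


def balanced_subset_eval(
    pos_probs,
    neg_pool_probs,
    runs: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    neg_indices: list[np.ndarray] | None = None,
) -> dict:
    """Evaluate on balanced subsets: all positives plus an equal-size random
    draw of negatives, repeated with a fresh draw each run (β = 1).

    Returns per-metric means and sample SDs, the per-run :class:`EvalResult`
    list, and the sampled negative indices (pass these back via
    ``neg_indices`` to evaluate another method on the same subsets, as the
    paired t-test requires).
    """
    pos_probs = np.asarray(pos_probs, dtype=float)
    neg_pool_probs = np.asarray(neg_pool_probs, dtype=float)
    n = pos_probs.size
    if neg_pool_probs.size < n:
        raise ValueError("negative pool smaller than the positive set")
    rng = np.random.default_rng(seed)
    if neg_indices is None:
        neg_indices = [
            rng.choice(neg_pool_probs.size, size=n, replace=False)
            for _ in range(runs)
        ]
    results = []
    for idx in neg_indices:
        probs = np.concatenate([pos_probs, neg_pool_probs[idx]])
        labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
        results.append(evaluate(labels, probs, beta=1.0, threshold=threshold))
    metrics = ["recall", "precision", "f_measure", "auc"]
    summary = {
        m: (
            float(np.mean([getattr(r, m) for r in results])),
            float(np.std([getattr(r, m) for r in results], ddof=1)),
        )
        for m in metrics
    }
    return {"summary": summary, "runs": results, "neg_indices": neg_indices}


def paired_ttest(metric_runs_a, metric_runs_b) -> float:
    """Two-tailed paired t-test p-value; identical vectors give p = 1.0."""
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def ablation_table(
    matrix,
    labels=None,
    features: list[str] | None = None,
    rf_config: RFConfig = RFConfig(),
    k: int = 10,
    fold_seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-feature-out CV table: an all-features row plus one row per
    subtracted feature, each carrying recall/precision/F(β=1)/AUC."""
    X, y = learning._as_xy(matrix, labels)
    if features is None:
        features = list(X.columns)
    rows = []
    subsets = [("all features", features)] + [
        (f"no {name}", [f for f in features if f != name]) for name in features
    ]
    for row_name, subset in subsets:
        oof = _oof_probs(X[subset], y, rf_config, k, fold_seed)
        res = evaluate(y.to_numpy(), oof, beta=1.0, threshold=threshold)
        rows.append({"subset": row_name, **res.to_dict()})
    return pd.DataFrame(rows)


def _oof_probs(X: pd.DataFrame, y: pd.Series, rf_config, k, fold_seed) -> np.ndarray:
    """Pooled out-of-fold probabilities (same protocol as kfold_cv_auc)."""
    from sklearn.model_selection import StratifiedKFold

    from .feature_matrix import FeatureMatrix, impute_missing, zscore_apply, zscore_fit

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        fm_train = impute_missing(FeatureMatrix(X.iloc[train_idx], X.iloc[train_idx].isna()))
        fm_test = impute_missing(FeatureMatrix(X.iloc[test_idx], X.iloc[test_idx].isna()))
        params = zscore_fit(fm_train)
        Xtr = zscore_apply(fm_train, params).values
        Xte = zscore_apply(fm_test, params).values
        clf = learning._fit_forest(Xtr.to_numpy(), y.iloc[train_idx].to_numpy(), rf_config)
        pos_col = list(clf.classes_).index(1)
        oof[test_idx] = clf.predict_proba(Xte.to_numpy())[:, pos_col]
    return oof


def imbalance_sweep(
    X_pos: pd.DataFrame,
    X_neg_pool: pd.DataFrame,
    multipliers: list[int] = (10, 20, 30, 40, 50),
    rf_config: RFConfig = RFConfig(),
    k: int = 10,
    fold_seed: int = 0,
    seed: int = 0,
    X_test: pd.DataFrame | None = None,
    y_test=None,
) -> pd.DataFrame:
    """CV (and optional held-out) AUC as the benign set grows to m x the
    deleterious set, m in ``multipliers``.

    Negatives are sampled from the pool without replacement per multiplier;
    a pool smaller than m·|pos| is capped with a warning.
    """
    rng = np.random.default_rng(seed)
    n_pos = len(X_pos)
    rows = []
    for m in multipliers:
        want = m * n_pos
        if want > len(X_neg_pool):
            warnings.warn(
                f"negative pool ({len(X_neg_pool)}) smaller than {want}; capped"
            )
            want = len(X_neg_pool)
        idx = rng.choice(len(X_neg_pool), size=want, replace=False)
        X = pd.concat([X_pos, X_neg_pool.iloc[idx]])
        y = pd.Series(
            np.concatenate([np.ones(n_pos, dtype=int), np.zeros(want, dtype=int)]),
            index=X.index,
        )
        row = {
            "multiplier": m,
            "n_neg": want,
            "cv_auc": kfold_cv_auc(X, y, rf_config, k, fold_seed),
        }
        if X_test is not None and y_test is not None:
            from .feature_matrix import FeatureMatrix, impute_missing, zscore_apply, zscore_fit

            fm = impute_missing(FeatureMatrix(X, X.isna()))
            params = zscore_fit(fm)
            Xn = zscore_apply(fm, params).values
            model = learning.train_rf(Xn, y, rf_config)
            fm_test = impute_missing(FeatureMatrix(X_test, X_test.isna()))
            Xt = zscore_apply(fm_test, params).values
            row["test_auc"] = learning.auc(
                np.asarray(y_test, dtype=int), model.predict_proba(Xt)
            )
        rows.append(row)
    return pd.DataFrame(rows)
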