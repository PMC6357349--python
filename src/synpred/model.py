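"""High-level modelling interface.

:class:`SynonymousVariantModel` holds a labeled feature matrix and the
fitting policy (grid search, backward feature selection, RF
hyperparameters); :meth:`~SynonymousVariantModel.fit` runs the training
protocol — zero-impute, z-score, optional grid search over
(ntree, mtry), optional sequential backward selection under the CV-AUC
criterion, and a final seeded random forest — and returns a
:class:`SynonymousVariantResults` carrying the fitted forest, the selection
trace, cross-validated AUC, feature importances, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, learning
from .feature_matrix import (
    FeatureMatrix,
    impute_missing,
    zscore_apply,
    zscore_fit,
)
from .learning import RFConfig, SelectionTrace, TrainedModel


class SynonymousVariantModel:
    """Random-forest deleteriousness model over a variant feature matrix.

    Parameters
    ----------
    matrix :
        A :class:`FeatureMatrix` with labels, or a features DataFrame
        (then ``labels`` is required).
    labels :
        Per-variant class labels (1 = deleterious, 0 = benign).
    """

    def __init__(self, matrix, labels=None):
        if isinstance(matrix, FeatureMatrix):
            self.matrix = matrix
            if labels is not None:
                self.matrix.labels = pd.Series(
                    np.asarray(labels, dtype=int), index=matrix.values.index
                )
        else:
            X = pd.DataFrame(matrix).astype(float)
            if labels is None:
                raise ValueError("labels are required with a plain DataFrame")
            self.matrix = FeatureMatrix(
                X,
                X.isna(),
                labels=pd.Series(np.asarray(labels, dtype=int), index=X.index),
            )
        if self.matrix.labels is None:
            raise ValueError("feature matrix carries no labels")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label"):
        """Build from a DataFrame whose ``label_col`` holds 0/1 classes."""
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y)

    def fit(
        self,
        rf_config: RFConfig | None = None,
        grid_search: bool = False,
        select_features: bool = False,
        k: int = 10,
        fold_seed: int = 0,
        ntree_grid: list[int] | None = None,
        mtry_grid: list[int] | None = None,
        selection_rf_config: RFConfig | None = None,
    ) -> "SynonymousVariantResults":
        """Run the training protocol and return fitted results.

        Order of operations: grid search (if requested) fixes (ntree, mtry)
        on the full feature set; backward selection (if requested) then
        prunes features under the fixed configuration; the final forest is
        trained on the zero-imputed, z-scored full training set.
        """
        X_raw = self.matrix.values
        y = self.matrix.labels
        config = rf_config or RFConfig()

        grid_table = None
        if grid_search:
            config, grid_table = learning.grid_search(
                X_raw,
                y,
                ntree_grid=ntree_grid,
                mtry_grid=mtry_grid,
                k=k,
                fold_seed=fold_seed,
                rf_seed=config.seed,
            )

        trace = None
        feature_subset = list(X_raw.columns)
        if select_features:
            trace = learning.sbs_select(
                X_raw,
                y,
                rf_config=selection_rf_config or config,
                k=k,
                fold_seed=fold_seed,
            )
            feature_subset = trace.final_subset

        X_sub = X_raw[feature_subset]
        cv_auc = learning.kfold_cv_auc(X_sub, y, config, k=k, fold_seed=fold_seed)

        fm = impute_missing(
            FeatureMatrix(X_sub, self.matrix.missing_mask[feature_subset])
        )
        norm_params = zscore_fit(fm)
        X_norm = zscore_apply(fm, norm_params).values
        config = RFConfig(
            ntree=config.ntree,
            mtry=min(config.mtry, len(feature_subset)),
            seed=config.seed,
        )
        trained = learning.train_rf(X_norm, y, config, norm_params=norm_params)
        return SynonymousVariantResults(
            model=self,
            trained=trained,
            cv_auc=cv_auc,
            selection=trace,
            grid_table=grid_table,
            k=k,
            fold_seed=fold_seed,
        )


@dataclass
class SynonymousVariantResults:
    """Fitted model: estimates, diagnostics, prediction and persistence."""

    model: SynonymousVariantModel
    trained: TrainedModel
    cv_auc: float
    selection: SelectionTrace | None = None
    grid_table: pd.DataFrame | None = None
    k: int = 10
    fold_seed: int = 0

    @property
    def feature_names(self) -> list[str]:
        return self.trained.feature_names

    @property
    def rf_config(self) -> RFConfig:
        return self.trained.config

    @property
    def feature_importances(self) -> pd.Series:
        """Mean-decrease-in-impurity importances of the final forest."""
        return pd.Series(
            self.trained.estimator.feature_importances_,
            index=self.feature_names,
            name="importance",
        ).sort_values(ascending=False)

    def predict(self, X, raw: bool = True) -> np.ndarray:
        """Deleteriousness probability for new variants.

        With ``raw=True`` (default) ``X`` is on the raw feature scale and is
        zero-imputed and normalised with the stored training parameters.
        """
        X = X.values if isinstance(X, FeatureMatrix) else pd.DataFrame(X)
        if raw:
            fm = impute_missing(FeatureMatrix(X, X.isna()))
            X = zscore_apply(fm, self.trained.norm_params).values
        return self.trained.predict_proba(X)

    def evaluate(self, X, labels, beta: float | None = None, threshold: float = 0.5):
        """Score a labeled set; β defaults to its rounded class ratio."""
        labels = np.asarray(labels, dtype=int)
        if beta is None:
            beta = evaluation.class_ratio_beta(
                int((labels == 0).sum()), int((labels == 1).sum())
            )
        return evaluation.evaluate(labels, self.predict(X), beta=beta, threshold=threshold)

    def save(self, path: str) -> None:
        learning.save_model(self.trained, path)

    def summary(self) -> str:
        """Plain-text fit summary (configuration, CV AUC, selection trace,
        top feature importances)."""
        y = self.model.matrix.labels
        lines = [
            "Synonymous variant deleteriousness model (random forest)",
            "=" * 56,
            f"n variants:          {len(y)}  "
            f"({int((y == 1).sum())} deleterious / {int((y == 0).sum())} benign)",
            f"features:            {len(self.feature_names)}",
            f"ntree / mtry / seed: {self.rf_config.ntree} / "
            f"{self.rf_config.mtry} / {self.rf_config.seed}",
            f"{self.k}-fold CV AUC:      {self.cv_auc:.3f}  (fold seed {self.fold_seed})",
        ]
        if self.selection is not None:
            removed = ", ".join(self.selection.removed) or "(none)"
            lines += [
                "",
                "backward selection:",
                f"  initial criterion  {self.selection.initial_criterion:.3f}",
                f"  final criterion    {self.selection.final_criterion:.3f}",
                f"  removed            {removed}",
            ]
        lines += ["", "feature importances:"]
        for name, imp in self.feature_importances.items():
            lines.append(f"  {name:<12} {imp:.3f}")
        return "\n".join(lines)
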