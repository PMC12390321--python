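"""The immunogenicity classifier: a random forest over the 118-dim
peptide features.

The forest follows the configuration that decouples presentation from
immunogenicity in this setting: 1000 trees, minimum samples-split of 3,
Gini splits, and no bootstrap sampling — every tree sees the full
training set and diversity comes only from per-split feature
subsampling (sqrt of the feature count by default).  Scores are the
mean leaf class-1 fraction across trees, in [0, 1], with higher values
indicating stronger immunogenic potential.

The module is organised as a model object (:class:`ImmunogenicityForest`)
whose :meth:`~ImmunogenicityForest.fit` returns a results object
carrying the fitted ensemble, per-feature importances and a summary
table; cross-validation hangs off the model object.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .encoding import (
    FEATURE_LABELS,
    GLOBAL_DESCRIPTOR_NAMES,
    N_COMPONENTS,
    N_FEATURES,
    N_SLOTS,
    ResidueEncoder,
    encode_peptides,
)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults are the model's
    published configuration)."""

    n_trees: int = 1000
    min_samples_split: int = 3
    split_criterion: str = "gini"
    bootstrap: bool = False
    features_per_split: int = math.floor(math.sqrt(N_FEATURES))  # 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if not 1 <= self.features_per_split <= N_FEATURES:
            raise ValueError(f"features_per_split must be in [1, {N_FEATURES}]")

    def to_sklearn(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_split=self.min_samples_split,
            criterion=self.split_criterion,
            bootstrap=self.bootstrap,
            max_features=self.features_per_split,
            random_state=self.seed,
            n_jobs=1,
        )


def _as_matrix(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    return X


class ImmunogenicityForest:
    """Immunogenicity model over encoded peptide features.

    Parameters
    ----------
    features : array-like, shape (n, 118)
        Ordered peptide feature vectors (see :mod:`neoim.encoding`).
    labels : array-like of {0, 1}
        1 = immunogenic (T-cell positive), 0 = presented only.
    config : ForestConfig, optional
    """

    def __init__(
        self,
        features: pd.DataFrame | np.ndarray,
        labels: Sequence[int],
        config: ForestConfig | None = None,
    ):
        X = _as_matrix(features)
        y = np.asarray(labels, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels have different lengths")
        if np.isnan(X).any():
            raise ValueError("features contain NaN")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required for training")
        if np.bincount(y).min() < 2:
            raise ValueError("need at least 2 instances per class")
        self.exog = X
        self.endog = y
        self.config = config or ForestConfig()
        if isinstance(features, pd.DataFrame):
            self.feature_names = tuple(map(str, features.columns))
        else:
            self.feature_names = tuple(FEATURE_LABELS[: X.shape[1]])

    @classmethod
    def from_peptides(
        cls,
        peptides: Sequence[str],
        labels: Sequence[int],
        encoder: ResidueEncoder,
        config: ForestConfig | None = None,
    ) -> "ImmunogenicityForest":
        return cls(encode_peptides(list(peptides), encoder), labels, config)

    def _fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.exog.tobytes())
        h.update(self.endog.tobytes())
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        return h.hexdigest()[:16]

    def fit(self) -> "ImmunogenicityForestResults":
        """Fit the forest on the full data; deterministic given the
        config seed."""
        estimator = self.config.to_sklearn()
        estimator.fit(self.exog, self.endog)
        return ImmunogenicityForestResults(
            model=self,
            estimator=estimator,
            training_fingerprint=self._fingerprint(),
        )

    def cross_validate(self, k: int = 10, seed: int | None = None) -> "CVResult":
        """Stratified k-fold cross-validation with out-of-fold scoring.

        Every instance is scored by a forest not trained on it; ROC AUC
        and PR AUC are computed on the concatenated out-of-fold scores.
        """
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > np.bincount(self.endog).min():
            raise ValueError("k exceeds the minority-class count")
        seed = self.config.seed if seed is None else seed
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        n = len(self.endog)
        fold_assignments = np.empty(n, dtype=int)
        oof = np.empty(n, dtype=float)
        for fold, (train_idx, test_idx) in enumerate(
            splitter.split(self.exog, self.endog)
        ):
            fold_assignments[test_idx] = fold
            estimator = self.config.to_sklearn()
            estimator.fit(self.exog[train_idx], self.endog[train_idx])
            oof[test_idx] = estimator.predict_proba(self.exog[test_idx])[:, 1]
        _, roc_auc = _metrics.roc_curve_auc(oof, self.endog)
        _, pr_auc = _metrics.pr_curve_ap(oof, self.endog)
        return CVResult(
            fold_assignments=fold_assignments,
            oof_scores=oof,
            roc_auc=roc_auc,
            pr_auc=pr_auc,
        )


@dataclass
class CVResult:
    """Out-of-fold cross-validation scores and headline metrics."""

    fold_assignments: np.ndarray
    oof_scores: np.ndarray
    roc_auc: float
    pr_auc: float


class ImmunogenicityForestResults:
    """Fitted forest: scoring, importances and summary."""

    def __init__(
        self,
        model: ImmunogenicityForest,
        estimator: RandomForestClassifier,
        training_fingerprint: str,
    ):
        self.model = model
        self.estimator = estimator
        self.config = model.config
        self.training_fingerprint = training_fingerprint
        self.feature_importances = estimator.feature_importances_
        self.encoder: ResidueEncoder | None = None  # attach for persistence

    def score(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Immunogenicity scores in [0, 1] (mean leaf class-1 fraction)."""
        X = _as_matrix(features)
        if X.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"expected {self.model.exog.shape[1]} features, got {X.shape[1]}"
            )
        return self.estimator.predict_proba(X)[:, 1]

    def score_peptides(
        self, peptides: Sequence[str], encoder: ResidueEncoder | None = None
    ) -> np.ndarray:
        encoder = encoder or self.encoder
        if encoder is None:
            raise ValueError("no residue encoder attached or supplied")
        return self.score(encode_peptides(list(peptides), encoder))

    def importance_by_group(self) -> pd.Series:
        """Aggregate importances over the 11 position slots and the 8
        global descriptors; the groups partition the mass (sum = 1)."""
        if len(self.feature_importances) != N_FEATURES:
            raise ValueError("grouping defined only for the 118-dim encoding")
        groups: dict[str, float] = {}
        for slot in range(N_SLOTS):
            block = self.feature_importances[
                slot * N_COMPONENTS : (slot + 1) * N_COMPONENTS
            ]
            groups[f"position_{slot + 1}"] = float(block.sum())
        tail = self.feature_importances[N_SLOTS * N_COMPONENTS :]
        for name, value in zip(GLOBAL_DESCRIPTOR_NAMES, tail):
            groups[name] = float(value)
        return pd.Series(groups, name="importance")

    def summary(self) -> str:
        c = self.config
        lines = [
            "Immunogenicity Random Forest Results",
            "=" * 52,
            f"Observations:        {len(self.model.endog)}",
            f"Positives:           {int(self.model.endog.sum())}",
            f"Features:            {self.model.exog.shape[1]}",
            f"Trees:               {c.n_trees}",
            f"Min samples split:   {c.min_samples_split}",
            f"Criterion:           {c.split_criterion}",
            f"Bootstrap:           {c.bootstrap}",
            f"Features per split:  {c.features_per_split}",
            f"Seed:                {c.seed}",
            f"Training hash:       {self.training_fingerprint}",
            "-" * 52,
            "Top feature groups by importance:",
        ]
        top = self.importance_by_group().sort_values(ascending=False).head(8)
        for name, value in top.items():
            lines.append(f"  {name:<20s} {value:.4f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Persist the fitted forest (and attached encoder) to disk."""
        joblib.dump(
            {
                "estimator": self.estimator,
                "config": asdict(self.config),
                "fingerprint": self.training_fingerprint,
                "feature_names": self.model.feature_names,
                "n_features": self.model.exog.shape[1],
                "encoder": self.encoder,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImmunogenicityForestResults":
        payload = joblib.load(path)
        config = ForestConfig(**payload["config"])
        # rebuild a minimal model shell for dimension checks
        shell = ImmunogenicityForest.__new__(ImmunogenicityForest)
        shell.exog = np.zeros((0, payload["n_features"]))
        shell.endog = np.zeros(0, dtype=int)
        shell.config = config
        shell.feature_names = tuple(payload["feature_names"])
        results = cls(
            model=shell,
            estimator=payload["estimator"],
            training_fingerprint=payload["fingerprint"],
        )
        results.feature_importances = payload["estimator"].feature_importances_
        results.encoder = payload["encoder"]
        return results
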