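"""Evaluation metrics: ROC/PR curves, top-k lift, Kruskal-Wallis with
eta-squared, and the benchmark exclusion filter.

ROC AUC equals the Mann-Whitney concordance probability with ties
counted 1/2; average precision is the step-wise (interpolation-free)
estimator.  The eta-squared effect size is the rank-based estimator
(H - k + 1) / (n - k), clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)


def _validate_scored(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def roc_curve_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve points and area under the curve.

    Raises on single-class input (the curve is undefined).
    """
    scores, labels = _validate_scored(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, float(auc(fpr, tpr))


def pr_curve_ap(scores, labels) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve points and step-sum average precision."""
    scores, labels = _validate_scored(scores, labels)
    if labels.sum() == 0:
        raise ValueError("average precision requires at least one positive")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    curve = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "threshold": np.append(thresholds, np.nan),
        }
    )
    return curve, float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class LiftResult:
    """Positives captured in the top score fraction."""

    k: int
    captured: int
    total_positives: int
    capture_rate: float


def lift_topk(scores, labels, fraction: float) -> LiftResult:
    """Count positives among the top ``ceil(fraction * n)`` scores.

    Ties are broken by stable input order, so the result is
    deterministic for any score vector.
    """
    scores, labels = _validate_scored(scores, labels)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(scores)
    k = int(np.ceil(fraction * n))
    top = np.argsort(-scores, kind="stable")[:k]
    captured = int(labels[top].sum())
    total = int(labels.sum())
    return LiftResult(
        k=k,
        captured=captured,
        total_positives=total,
        capture_rate=captured / total if total else float("nan"),
    )


@dataclass(frozen=True)
class KruskalResult:
    H: float
    p_value: float
    eta_squared: float
    n_groups: int
    n_total: int


def kruskal_wallis_eta2(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with the rank eta-squared effect
    size (H - k + 1) / (n - k), clipped to [0, 1]."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    H, p = stats.kruskal(*samples)
    k = len(samples)
    n = len(values)
    eta2 = float(np.clip((H - k + 1) / (n - k), 0.0, 1.0))
    return KruskalResult(H=float(H), p_value=float(p), eta_squared=eta2,
                         n_groups=k, n_total=n)


def filter_benchmark_peptides(
    table: pd.DataFrame,
    label_col: str = "label",
    positive_elsewhere_col: str = "positive_elsewhere",
) -> pd.DataFrame:
    """Benchmark exclusion filter: drop non-immunogenic peptides that
    were recorded as positive in an immunogenicity assay elsewhere.

    Positives (label 1) are kept unconditionally; negatives flagged in
    ``positive_elsewhere_col`` are removed, since their negative status
    is contradicted.
    """
    if label_col not in table or positive_elsewhere_col not in table:
        raise ValueError(
            f"table needs columns {label_col!r} and {positive_elsewhere_col!r}"
        )
    flagged = (table[label_col] == 0) & table[positive_elsewhere_col].astype(bool)
    return table.loc[~flagged].reset_index(drop=True)


def bias_test(
    table: pd.DataFrame,
    score_col: str = "score",
    factors: tuple[str, ...] = ("hla", "length"),
) -> pd.DataFrame:
    """Kruskal-Wallis bias test of score distributions across each
    factor (e.g. HLA allele, peptide length); one row per factor with
    H, p and eta-squared."""
    rows = []
    for factor in factors:
        if factor not in table:
            raise ValueError(f"missing factor column {factor!r}")
        res = kruskal_wallis_eta2(table[score_col].to_numpy(), table[factor].to_numpy())
        rows.append(
            {
                "factor": factor,
                "H": res.H,
                "p_value": res.p_value,
                "eta_squared": res.eta_squared,
                "n_groups": res.n_groups,
                "n": res.n_total,
            }
        )
    return pd.DataFrame(rows)
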