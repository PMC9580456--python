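"""Selection diagnostics: confusion matrices, rank-coincidence AUC, MA plots."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .decomposition import ExpressionMatrix

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "rank_coincidence_auc",
    "maplot",
]

CATEGORY_LABELS = ("not_selected", "selected_0.1", "selected_0.01")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of truth (outlier/DEG) vs selection."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion(truth: np.ndarray, selected: np.ndarray) -> ConfusionMatrix:
    """Cross-tabulate ground-truth labels against selection flags."""
    truth = np.asarray(truth, dtype=bool)
    selected = np.asarray(selected, dtype=bool)
    if truth.shape != selected.shape:
        raise ValueError("truth and selection vectors must have equal length")
    return ConfusionMatrix(
        tn=int(np.sum(~truth & ~selected)),
        fp=int(np.sum(~truth & selected)),
        fn=int(np.sum(truth & ~selected)),
        tp=int(np.sum(truth & selected)),
    )


def rank_coincidence_auc(
    p_reference: np.ndarray, p_predictor: np.ndarray, top_k: int = 1000
) -> float:
    """AUC for retrieving the reference method's top-k features by another's P.

    The ``top_k`` features with the smallest ``p_reference`` are the
    positives; ``-p_predictor`` is the retrieval score.  Computed by the
    rank-sum (Mann-Whitney) identity with average ranks on ties, so any
    strictly increasing transform of the predictor leaves it unchanged.
    """
    p_reference = np.asarray(p_reference, dtype=float)
    p_predictor = np.asarray(p_predictor, dtype=float)
    if p_reference.shape != p_predictor.shape:
        raise ValueError("P-value vectors must have equal length")
    n = p_reference.size
    if not 0 < top_k < n:
        raise ValueError(f"top_k must be in (0, {n}), got {top_k}")
    order = np.argsort(p_reference, kind="stable")
    positive = np.zeros(n, bool)
    positive[order[:top_k]] = True
    return float(roc_auc_score(positive, -p_predictor))


def maplot(
    x_raw: ExpressionMatrix,
    class_labels: np.ndarray,
    adjusted_p: np.ndarray,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene MA-plot coordinates with selection categories.

    A (mean log expression) is ``mean_j log2(x_ij + pseudocount)`` over all
    samples; M (log fold change) is the class-A mean log2 minus the class-B
    mean log2 with the same pseudocount.  Categories follow the adjusted-P
    cutoffs 0.01 (strong) and 0.1 (weak).
    """
    class_labels = np.asarray(class_labels, dtype=bool)
    if class_labels.size != x_raw.n_samples:
        raise ValueError("class labels must match the number of samples")
    if class_labels.all() or not class_labels.any():
        raise ValueError("class labels must define two nonempty groups")
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    if adjusted_p.size != x_raw.n_features:
        raise ValueError("adjusted P vector must match the number of features")
    logx = np.log2(x_raw.values + pseudocount)
    a = logx.mean(axis=1)
    m = logx[:, class_labels].mean(axis=1) - logx[:, ~class_labels].mean(axis=1)
    category = np.where(
        adjusted_p <= 0.01,
        CATEGORY_LABELS[2],
        np.where(adjusted_p <= 0.1, CATEGORY_LABELS[1], CATEGORY_LABELS[0]),
    )
    return pd.DataFrame(
        {
            "feature_id": x_raw.feature_ids,
            "A": a,
            "M": m,
            "adjusted_p": adjusted_p,
            "category": category,
        }
    )
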