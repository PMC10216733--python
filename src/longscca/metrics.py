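"""Evaluation metrics: canonical correlation, regression R^2, feature
ranking, support recovery, and clustering indices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .containers import OmicsMatrix

__all__ = [
    "EvaluationReport",
    "ccc",
    "r2_score",
    "top_k_features",
    "support_recovery",
    "clustering_indices",
]


@dataclass
class EvaluationReport:
    """Collected evaluation results for one fitted canonical model."""

    ccc_per_time: list[float] = field(default_factory=list)
    mean_ccc: float = float("nan")
    top_features: dict = field(default_factory=dict)
    support_metrics: dict = field(default_factory=dict)
    clustering_scores: dict = field(default_factory=dict)


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, OmicsMatrix) else np.asarray(M, dtype=float)


def ccc(X, u, Yt, vt) -> float:
    """Pearson canonical correlation coefficient corr(Xu, Yt vt)."""
    xu = _values(X) @ np.asarray(u, dtype=float)
    yv = _values(Yt) @ np.asarray(vt, dtype=float)
    if np.std(xu) == 0 or np.std(yv) == 0:
        raise ValueError("undefined metric: zero-variance projected scores")
    return float(np.corrcoef(xu, yv)[0, 1])


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination 1 - MSE/Var.

    Both MSE and Var use the population divisor n, so the ratio equals
    SSE/SST and agrees with the usual definition.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    var = np.mean((y_true - y_true.mean()) ** 2)
    if var == 0:
        raise ValueError("undefined metric: constant y_true")
    mse = np.mean((y_true - y_pred) ** 2)
    return float(1.0 - mse / var)


def top_k_features(weights, names, k: int):
    """Top-k (name, |weight|) pairs, ties broken by name for determinism."""
    weights = np.asarray(weights, dtype=float)
    names = list(names)
    if k > len(weights):
        raise ValueError("k exceeds the number of features")
    order = sorted(range(len(weights)), key=lambda i: (-abs(weights[i]), names[i]))
    return [(names[i], float(abs(weights[i]))) for i in order[:k]]


def support_recovery(estimated, true, zero_tol: float = 1e-8):
    """Precision/recall/F1 of the estimated nonzero support vs the truth.

    Supports are |w| > zero_tol. Empty-set conventions: precision is 0 when
    nothing is selected, recall is 0 when the true support is empty but
    something was selected; F1 is 0 whenever precision + recall is 0.
    """
    est = np.abs(np.asarray(estimated, dtype=float)) > zero_tol
    tru = np.abs(np.asarray(true, dtype=float)) > zero_tol
    if est.shape != tru.shape:
        raise ValueError("length mismatch")
    tp = int((est & tru).sum())
    precision = tp / est.sum() if est.sum() else 0.0
    recall = tp / tru.sum() if tru.sum() else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return float(precision), float(recall), float(f1)


def _pairwise_prf(labels_true, labels_pred):
    """Pair-counting precision/recall/F of a predicted clustering."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    n = len(labels_true)
    same_t = labels_true[:, None] == labels_true[None, :]
    same_p = labels_pred[:, None] == labels_pred[None, :]
    iu = np.triu_indices(n, k=1)
    st, sp = same_t[iu], same_p[iu]
    tp = int((st & sp).sum())
    precision = tp / sp.sum() if sp.sum() else 0.0
    recall = tp / st.sum() if st.sum() else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def clustering_indices(data, labels_pred, labels_true=None) -> dict:
    """Internal and (optionally) external clustering quality indices.

    Internal: silhouette (the "contour coefficient"), Calinski-Harabasz,
    Davies-Bouldin.  External (when true labels are given): pair-counting
    F-score/precision/recall, normalized mutual information, adjusted Rand.
    """
    X = _values(data)
    labels_pred = np.asarray(labels_pred)
    if len(np.unique(labels_pred)) < 2:
        raise ValueError("undefined metric: internal indices need >= 2 clusters")
    out = {
        "silhouette": float(skm.silhouette_score(X, labels_pred)),
        "calinski_harabasz": float(skm.calinski_harabasz_score(X, labels_pred)),
        "davies_bouldin": float(skm.davies_bouldin_score(X, labels_pred)),
    }
    if labels_true is not None:
        labels_true = np.asarray(labels_true)
        precision, recall, f = _pairwise_prf(labels_true, labels_pred)
        out.update(
            {
                "f_score": float(f),
                "precision": float(precision),
                "recall": float(recall),
                "nmi": float(skm.normalized_mutual_info_score(labels_true, labels_pred)),
                "ari": float(skm.adjusted_rand_score(labels_true, labels_pred)),
            }
        )
    return out
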