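"""KNN hypergraphs over samples and their normalized Laplacians.

A hypergraph generalizes a graph by letting an edge (hyperedge) join any
number of vertices.  Here each sample is a vertex and each sample spawns one
hyperedge containing itself (the centroid) and its k nearest neighbors, so
the incidence matrix H is N x N with column sums k+1.  With W the diagonal
of hyperedge weights, Dv the vertex degrees d(v) = sum_e w(e) H(v,e) and De
the hyperedge degrees delta(e) = sum_v H(v,e), the normalized Laplacian is

    L = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}

which is symmetric, positive semidefinite, and annihilates Dv^{1/2} 1.
Penalizing x^T L x smooths a per-sample score x over the hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .containers import OmicsMatrix

__all__ = ["Hypergraph", "build_knn_hypergraph", "vertex_degrees", "laplacian"]


@dataclass
class Hypergraph:
    """Incidence-matrix representation with weights and degree diagonals."""

    incidence: np.ndarray  # N x Ne binary
    edge_weights: np.ndarray  # length Ne, positive

    def __post_init__(self) -> None:
        H = np.asarray(self.incidence, dtype=float)
        if not np.isin(H, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0/1")
        if (H.sum(axis=0) == 0).any():
            raise ValueError("empty hyperedge")
        if (H.sum(axis=1) == 0).any():
            raise ValueError("isolated vertex (member of no hyperedge)")
        w = np.asarray(self.edge_weights, dtype=float)
        if w.shape != (H.shape[1],):
            raise ValueError("edge_weights length must equal number of hyperedges")
        if (w <= 0).any():
            raise ValueError("edge weights must be positive")
        self.incidence = H
        self.edge_weights = w

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        return vertex_degrees(self.incidence, self.edge_weights)

    @property
    def edge_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)


def build_knn_hypergraph(
    data: OmicsMatrix | np.ndarray,
    k: int = 5,
    metric: str = "euclidean",
    weighting: str = "uniform",
) -> Hypergraph:
    """One hyperedge per sample: the sample plus its k nearest neighbors.

    Parameters
    ----------
    data : OmicsMatrix or array
        Samples x features; pairwise distances are taken over feature values.
    k : int
        Neighbors per hyperedge; every hyperedge degree is k+1.
    metric : str
        Any metric accepted by scipy ``cdist``.
    weighting : {"uniform", "heat"}
        Uniform weight 1 per hyperedge, or a heat-kernel weight
        w(e) = sum_{v in e} exp(-d(v, centroid)^2 / sbar^2) with sbar the
        mean pairwise distance.

    Distance ties are broken by ascending sample index so duplicated rows
    yield a deterministic hypergraph.
    """
    X = data.values if isinstance(data, OmicsMatrix) else np.asarray(data, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1, got k={k} for N={n}")
    if np.isnan(X).any():
        raise ValueError("input contains NaNs")

    D = cdist(X, X, metric=metric)
    # stable argsort on (distance, index) pairs -> deterministic ties
    order = np.argsort(D, axis=1, kind="stable")

    H = np.zeros((n, n))
    for i in range(n):
        members = order[i, : k + 1]
        if i not in members:  # duplicates may displace the centroid itself
            members = np.concatenate([[i], members[:k]])
        H[members, i] = 1.0

    if weighting == "uniform":
        w = np.ones(n)
    elif weighting == "heat":
        pair = pdist(X, metric=metric)
        sbar = pair.mean() if pair.size else 1.0
        sbar = sbar if sbar > 0 else 1.0
        w = np.array(
            [np.exp(-(D[H[:, i] > 0, i] ** 2) / sbar**2).sum() for i in range(n)]
        )
    else:
        raise ValueError(f"unknown weighting '{weighting}'")
    return Hypergraph(H, w)


def vertex_degrees(H: np.ndarray, w: np.ndarray) -> np.ndarray:
    """d(v) = sum_e w(e) H(v, e)."""
    H = np.asarray(H, dtype=float)
    w = np.asarray(w, dtype=float)
    if H.shape[1] != w.shape[0]:
        raise ValueError("shape mismatch between incidence and weights")
    if (w < 0).any():
        raise ValueError("negative edge weights")
    return H @ w


def laplacian(hg: Hypergraph) -> np.ndarray:
    """Normalized hypergraph Laplacian L = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}."""
    H, w = hg.incidence, hg.edge_weights
    dv = vertex_degrees(H, w)
    zero = np.flatnonzero(dv <= 0)
    if zero.size:
        raise ValueError(f"degenerate input: vertex {zero[0]} has zero degree")
    de = H.sum(axis=0)
    # Theta = C C^T with C = Dv^{-1/2} H sqrt(W/De): exactly symmetric form
    C = (H * np.sqrt(w / de)[None, :]) / np.sqrt(dv)[:, None]
    theta = C @ C.T
    theta = (theta + theta.T) / 2.0
    return np.eye(hg.n_vertices) - theta
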