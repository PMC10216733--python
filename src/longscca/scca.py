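"""Temporally-constrained group-sparse CCA with hypergraph smoothness.

The estimator couples a static gene-expression view ``X`` (n x q) with T
longitudinal phenotype views ``Y_t`` (n x p) through a gene weight vector
``u`` and per-time phenotype weight vectors ``V = [v_1 .. v_T]`` (p x T),
minimizing

    f(u, V) = - sum_t u^T X^T Y_t v_t            (negated cross-covariance)
              + lam1 ||u||_1                      (gene sparsity)
              + lam2 ||V||_{2,1}                  (row sparsity: ROI selection
                                                   shared across time)
              + lamt sum_{t<T} ||v_{t+1} - v_t||  (temporal smoothness)
              + beta1 (Xu)^T L1 (Xu)              (hypergraph smoothness of
              + beta2 sum_t (Y_t v_t)^T L2_t (Y_t v_t)   projected samples)

subject to the scale constraints ||Xu||_2 <= 1 and ||Y_t v_t||_2 <= 1 that
make the Pearson canonical correlation of the projections scale-free.
Setting beta1 = beta2 = 0 recovers the temporally-constrained group-sparse
CCA baseline without hypergraph terms.

Optimization is alternating block minimization.  Each block subproblem is
solved through a Lagrangian surrogate in which the scale constraint is
replaced by the ridge-like term (1/2)||Xu||^2 (resp. (1/2)||Y_t v_t||^2),
giving a smooth-plus-separable problem amenable to proximal gradient
(FISTA); candidates are then projected back into the feasible set and a
monotone safeguard accepts a candidate only if it does not increase the
objective, so the recorded objective trace is non-increasing by
construction.  In the penalty-free single-time case the block updates
reduce to u = (X^T X)^{-1} X^T Y v (rescaled), i.e. exact alternating
classical CCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import LongitudinalPhenotype, OmicsMatrix

__all__ = [
    "PenaltyConfig",
    "CanonicalModel",
    "soft_threshold",
    "objective",
    "update_u",
    "update_V",
    "fit",
    "fit_tgscca",
    "score_ccc",
]

_RIDGE = 1e-10  # relative ridge for rank-deficient direct solves


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty weights and optimization schedule for the canonical model."""

    lam1: float = 0.0
    lam2: float = 0.0
    lamt: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    max_iter: int = 100
    tol: float = 1e-5
    inner_max_iter: int = 200
    inner_tol: float = 1e-8
    fused_norm: str = "l2"
    cov: str = "auto"

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "lamt", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.inner_max_iter < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.fused_norm not in ("l2", "l1"):
            raise ValueError("fused_norm must be 'l2' or 'l1'")
        if self.cov not in ("auto", "full", "diag"):
            raise ValueError("cov must be 'auto', 'full' or 'diag'")


@dataclass
class CanonicalModel:
    """Fitted canonical weights with diagnostics."""

    u: np.ndarray  # gene weights, length q
    V: np.ndarray  # phenotype weights, p x T
    objective_trace: list[float] = field(default_factory=list)
    hyperparams: PenaltyConfig = field(default_factory=PenaltyConfig)
    converged: bool = False
    n_iter: int = 0
    gene_features: list[str] | None = None
    pheno_features: list[str] | None = None
    diagnostics: dict = field(default_factory=dict)
    x_stats: tuple | None = None  # (mean, std) used to standardize X
    y_stats: list | None = None  # per-time (mean, std) for the Y views


def soft_threshold(z: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(z) * max(|z| - lam, 0): prox of lam * ||.||_1."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def _as_arrays(X, Ys):
    X = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    if isinstance(Ys, LongitudinalPhenotype):
        Ys = Ys.arrays()
    Ys = [y.values if isinstance(y, OmicsMatrix) else np.asarray(y, dtype=float) for y in Ys]
    return X, Ys


def _fused_penalty(V: np.ndarray, norm: str) -> float:
    diffs = np.diff(V, axis=1)
    if norm == "l2":
        return float(np.linalg.norm(diffs, axis=0).sum())
    return float(np.abs(diffs).sum())


def objective(u, V, X, Ys, L1, L2s, cfg: PenaltyConfig) -> float:
    """Evaluate the minimization objective f(u, V) (scale constraints aside)."""
    X, Ys = _as_arrays(X, Ys)
    u = np.asarray(u, dtype=float)
    V = np.asarray(V, dtype=float)
    T = len(Ys)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[1] != T:
        raise ValueError("V must have one column per time point")
    if X.shape[1] != u.shape[0]:
        raise ValueError("u length must match gene feature count")
    if any(y.shape[0] != X.shape[0] for y in Ys):
        raise ValueError("views must share sample count")
    if any(y.shape[1] != V.shape[0] for y in Ys):
        raise ValueError("V rows must match phenotype feature count")

    xu = X @ u
    val = 0.0
    for t in range(T):
        yv = Ys[t] @ V[:, t]
        val -= float(xu @ yv)
        if cfg.beta2 > 0 and L2s is not None:
            val += cfg.beta2 * float(yv @ (L2s[t] @ yv))
    val += cfg.lam1 * float(np.abs(u).sum())
    val += cfg.lam2 * float(np.linalg.norm(V, axis=1).sum())
    val += cfg.lamt * _fused_penalty(V, cfg.fused_norm)
    if cfg.beta1 > 0 and L1 is not None:
        val += cfg.beta1 * float(xu @ (L1 @ xu))
    return val


def _block_obj_u(u, c, M1, beta1, lam1):
    val = -float(u @ c) + lam1 * float(np.abs(u).sum())
    if beta1 > 0 and M1 is not None:
        val += beta1 * float(u @ (M1 @ u))
    return val


def _fista_l1(Q, c, lam1, x0, max_iter, tol):
    """Minimize -x^T c + (1/2) x^T Q x + lam1 ||x||_1 by FISTA."""
    L = float(np.linalg.eigvalsh(Q)[-1])
    if L <= 0:
        return soft_threshold(c, lam1)
    step = 1.0 / L
    x = x0.copy()
    y = x0.copy()
    tk = 1.0
    for _ in range(max_iter):
        grad = Q @ y - c
        x_new = soft_threshold(y - step * grad, step * lam1)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * tk**2)) / 2.0
        y = x_new + ((tk - 1.0) / t_new) * (x_new - x)
        delta = np.linalg.norm(x_new - x)
        x, tk = x_new, t_new
        if delta <= tol * max(1.0, np.linalg.norm(x)):
            break
    return x


def _solve_quad(Q, c):
    """Least-squares solve of Q x = c (Q PSD, possibly singular)."""
    n = Q.shape[0]
    ridge = _RIDGE * max(np.trace(Q) / n, 1.0)
    return np.linalg.solve(Q + ridge * np.eye(n), c)


def update_u(u, V, X, Ys, L1, cfg: PenaltyConfig, _cache: dict | None = None):
    """Block update of the gene weights with V fixed.

    Solves the Lagrangian surrogate, then picks the best feasible candidate
    among {previous u, feasibility-scaled solution, boundary-scaled
    solution, 0} under the block objective, guaranteeing descent.
    """
    X, Ys = _as_arrays(X, Ys)
    u = np.asarray(u, dtype=float)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] != Ys[0].shape[1]:
        V = V.T
    c = np.zeros(X.shape[1])
    for t in range(len(Ys)):
        c += X.T @ (Ys[t] @ V[:, t])
    if not np.isfinite(c).all():
        raise FloatingPointError("non-finite gradient in u update")

    M1 = None
    if cfg.beta1 > 0 and L1 is not None:
        M1 = X.T @ (L1 @ X)

    # null condition: 0 is a global block minimizer iff ||c||_inf <= lam1
    if cfg.lam1 > 0 and np.abs(c).max() <= cfg.lam1 * (1 + 1e-12):
        return np.zeros_like(u)

    cache = _cache if _cache is not None else {}
    if "Qu" not in cache:
        # Lagrangian surrogate for the scale constraint: the Gram matrix
        # when it is trustworthy (n comfortably above the block dimension),
        # else its diagonal -- the standard sparse-CCA surrogate that avoids
        # whitening through a near-singular covariance.
        gram = X.T @ X
        use_full = cfg.cov == "full" or (
            cfg.cov == "auto" and X.shape[0] >= 3 * X.shape[1]
        )
        Q = gram if use_full else np.diag(np.diag(gram))
        if M1 is not None:
            Q = Q + 2.0 * cfg.beta1 * M1
        diagonal = not use_full and M1 is None
        cache["Qu"] = (Q, diagonal)
    Q, diagonal = cache["Qu"]

    if diagonal:
        d = np.diag(Q).copy()
        d[d <= 0] = 1.0
        cand = soft_threshold(c, cfg.lam1) / d
    elif cfg.lam1 == 0:
        cand = _solve_quad(Q, c)
    else:
        cand = _fista_l1(Q, c, cfg.lam1, u, cfg.inner_max_iter, cfg.inner_tol)

    candidates = [u, np.zeros_like(u)]
    norm = np.linalg.norm(X @ cand)
    if norm > 0:
        candidates.append(cand / norm)        # boundary ||Xu|| = 1
        if norm <= 1.0:
            candidates.append(cand)           # interior solution as-is
    best = min(candidates, key=lambda z: _block_obj_u(z, c, M1, cfg.beta1, cfg.lam1))
    return best.copy()


def _block_obj_V(V, B, Ys, L2s, cfg):
    T = V.shape[1]
    val = 0.0
    for t in range(T):
        yv = Ys[t] @ V[:, t]
        val -= float(B[:, t] @ V[:, t])
        if cfg.beta2 > 0 and L2s is not None:
            val += cfg.beta2 * float(yv @ (L2s[t] @ yv))
    val += cfg.lam2 * float(np.linalg.norm(V, axis=1).sum())
    val += cfg.lamt * _fused_penalty(V, cfg.fused_norm)
    return val


def _prox_rows_l21(V, tau):
    norms = np.linalg.norm(V, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(1.0 - tau / norms[nz], 0.0)
    return V * scale[:, None]


def _prox_fused_chain(V, tau, norm, n_cycles=20, tol=1e-8):
    """Cyclic pairwise proximal passes for tau * sum_t ||v_{t+1} - v_t||."""
    V = V.copy()
    T = V.shape[1]
    for _ in range(n_cycles):
        change = 0.0
        for t in range(T - 1):
            a, b = V[:, t], V[:, t + 1]
            m = (a + b) / 2.0
            d = b - a
            if norm == "l2":
                nd = np.linalg.norm(d)
                d_new = d * max(1.0 - 2.0 * tau / nd, 0.0) if nd > 0 else d
            else:
                d_new = soft_threshold(d, 2.0 * tau)
            change = max(change, float(np.abs(d_new - d).max(initial=0.0)))
            V[:, t] = m - d_new / 2.0
            V[:, t + 1] = m + d_new / 2.0
        if change <= tol:
            break
    return V


def update_V(u, V, X, Ys, L2s, cfg: PenaltyConfig, _cache: dict | None = None):
    """Block update of the phenotype weight matrix with u fixed.

    Proximal gradient on the Lagrangian surrogate; the composite nonsmooth
    term (row-wise L2,1 + temporal fused chain) is handled by alternating
    proximal steps.  The same monotone safeguard as :func:`update_u`
    applies; feasibility uses a common column scaling so fused structure is
    preserved.
    """
    X, Ys = _as_arrays(X, Ys)
    u = np.asarray(u, dtype=float)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] != Ys[0].shape[1]:
        V = V.T
    T = len(Ys)
    xu = X @ u
    B = np.column_stack([Ys[t].T @ xu for t in range(T)])
    if not np.isfinite(B).all():
        raise FloatingPointError("non-finite gradient in V update")

    # null condition for the row-sparsity penalty
    if cfg.lam2 > 0 and np.linalg.norm(B, axis=1).max() <= cfg.lam2 * (1 + 1e-12):
        return np.zeros_like(V)

    cache = _cache if _cache is not None else {}
    if "Av" not in cache:
        use_full = cfg.cov == "full" or (
            cfg.cov == "auto" and Ys[0].shape[0] >= 3 * Ys[0].shape[1]
        )
        As = []
        for t in range(T):
            gram = Ys[t].T @ Ys[t]
            A = gram if use_full else np.diag(np.diag(gram))
            if cfg.beta2 > 0 and L2s is not None:
                A = A + 2.0 * cfg.beta2 * (Ys[t].T @ (L2s[t] @ Ys[t]))
            As.append(A)
        Ls = max(float(np.linalg.eigvalsh(A)[-1]) for A in As)
        cache["Av"] = (As, Ls)
    As, Lsmooth = cache["Av"]

    if cfg.lam2 == 0 and cfg.lamt == 0:
        cand = np.column_stack([_solve_quad(As[t], B[:, t]) for t in range(T)])
    else:
        step = 1.0 / max(Lsmooth, 1e-12)
        W = V.copy()
        Z = V.copy()
        tk = 1.0
        for _ in range(cfg.inner_max_iter):
            grad = np.column_stack([As[t] @ Z[:, t] - B[:, t] for t in range(T)])
            G = Z - step * grad
            W_new = _prox_rows_l21(G, step * cfg.lam2) if cfg.lam2 > 0 else G
            if cfg.lamt > 0 and T > 1:
                W_new = _prox_fused_chain(W_new, step * cfg.lamt, cfg.fused_norm)
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * tk**2)) / 2.0
            Z = W_new + ((tk - 1.0) / t_new) * (W_new - W)
            delta = np.linalg.norm(W_new - W)
            W, tk = W_new, t_new
            if delta <= cfg.inner_tol * max(1.0, np.linalg.norm(W)):
                break
        cand = W

    candidates = [V, np.zeros_like(V)]
    max_norm = max(np.linalg.norm(Ys[t] @ cand[:, t]) for t in range(T))
    if max_norm > 0:
        candidates.append(cand / max_norm)    # common scale -> boundary
        if max_norm <= 1.0:
            candidates.append(cand)
    best = min(candidates, key=lambda Z: _block_obj_V(Z, B, Ys, L2s, cfg))
    return best.copy()


def _standardize_inplace(M: np.ndarray, tag: str) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit Euclidean norm.

    Unit-norm columns put the cross-view gradient entries on Pearson
    correlation scale (in [-1, 1]), so the sparsity penalties lam1, lam2
    act on a data-size-free scale.  CCC is invariant to the choice.
    """
    mu = M.mean(axis=0)
    sd = M.std(axis=0) * np.sqrt(M.shape[0])
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{tag}: {int(const.sum())} constant feature(s) carry no signal "
            "and receive zero weight",
            stacklevel=3,
        )
        sd = np.where(const, 1.0, sd)
    M -= mu
    M /= sd
    return mu, sd


def fit(X, Ys, L1=None, L2s=None, cfg: PenaltyConfig | None = None,
        standardize: bool = True) -> CanonicalModel:
    """Fit the hypergraph-regularized temporally-constrained sparse CCA.

    Parameters
    ----------
    X : array or OmicsMatrix, n x q
        Gene-expression view.
    Ys : sequence of arrays / OmicsMatrix, or LongitudinalPhenotype
        T phenotype views, each n x p, in time order.
    L1 : array, optional
        n x n hypergraph Laplacian for the gene view (used when beta1 > 0).
    L2s : sequence of arrays, optional
        Per-time n x n Laplacians for the phenotype views (beta2 > 0).
    cfg : PenaltyConfig
        Penalties and schedule.
    standardize : bool
        Column-standardize views before fitting (constant columns get zero
        weight, with a warning).

    Initialization is the rank-1 SVD of X^T Ybar with Ybar the time-mean
    phenotype view; every v_t starts at the common right singular vector.
    Alternates the u and V block updates until the relative objective
    change drops below ``cfg.tol``.  At return u is rescaled so
    ||Xu|| = 1 and V by a common factor so max_t ||Y_t v_t|| = 1
    (when nonzero), keeping every scale constraint satisfied.
    """
    cfg = cfg or PenaltyConfig()
    gene_names = list(X.feature_names) if isinstance(X, OmicsMatrix) else None
    pheno_names = (
        list(Ys.feature_names) if isinstance(Ys, LongitudinalPhenotype) else None
    )
    X, Ys = _as_arrays(X, Ys)
    X = X.copy()
    Ys = [y.copy() for y in Ys]
    x_stats, y_stats = None, None
    if standardize:
        x_stats = _standardize_inplace(X, "gene view")
        y_stats = [
            _standardize_inplace(y, f"phenotype view t={t + 1}")
            for t, y in enumerate(Ys)
        ]

    n, q = X.shape
    p = Ys[0].shape[1]
    T = len(Ys)

    ybar = np.mean(Ys, axis=0)
    U0, _, Vt0 = np.linalg.svd(X.T @ ybar, full_matrices=False)
    u = U0[:, 0]
    v = Vt0[0]
    nx = np.linalg.norm(X @ u)
    u = u / nx if nx > 0 else u
    V = np.tile(v[:, None], (1, T))
    for t in range(T):
        ny = np.linalg.norm(Ys[t] @ V[:, t])
        if ny > 0:
            V[:, t] /= ny
    # common scale so every constraint holds at start
    max_ny = max(np.linalg.norm(Ys[t] @ V[:, t]) for t in range(T))
    if max_ny > 1:
        V /= max_ny

    cache: dict = {}
    trace = [objective(u, V, X, Ys, L1, L2s, cfg)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        u = update_u(u, V, X, Ys, L1, cfg, _cache=cache)
        V = update_V(u, V, X, Ys, L2s, cfg, _cache=cache)
        obj = objective(u, V, X, Ys, L1, L2s, cfg)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= cfg.tol * max(1.0, abs(prev)):
            converged = True
            break

    diagnostics = {}
    nx = np.linalg.norm(X @ u)
    if nx > 0:
        u = u / nx
    max_ny = max(np.linalg.norm(Ys[t] @ V[:, t]) for t in range(T))
    if max_ny > 0:
        V = V / max_ny
    if nx == 0 and max_ny == 0:
        diagnostics["all_zero_solution"] = True

    return CanonicalModel(
        u=u,
        V=V,
        objective_trace=trace,
        hyperparams=cfg,
        converged=converged,
        n_iter=it,
        gene_features=gene_names,
        pheno_features=pheno_names,
        diagnostics=diagnostics,
        x_stats=x_stats,
        y_stats=y_stats,
    )


def score_ccc(model: CanonicalModel, X, Ys) -> list[float]:
    """Per-time canonical correlations of a fitted model on (held-out) data.

    New data are standardized with the statistics stored at fit time, so
    train and test projections live on the same scale.
    """
    from .metrics import ccc as _ccc

    X, Ys = _as_arrays(X, Ys)
    if model.x_stats is not None:
        mu, sd = model.x_stats
        X = (X - mu) / sd
        Ys = [(y - m) / s for y, (m, s) in zip(Ys, model.y_stats)]
    return [_ccc(X, model.u, Ys[t], model.V[:, t]) for t in range(len(Ys))]


def fit_tgscca(X, Ys, cfg: PenaltyConfig | None = None,
               standardize: bool = True) -> CanonicalModel:
    """The temporally-constrained group-sparse CCA baseline.

    Identical to :func:`fit` with the hypergraph penalties switched off
    (beta1 = beta2 = 0); no Laplacians are required.
    """
    cfg = cfg or PenaltyConfig()
    import dataclasses as _dc

    cfg0 = _dc.replace(cfg, beta1=0.0, beta2=0.0)
    return fit(X, Ys, L1=None, L2s=None, cfg=cfg0, standardize=standardize)
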