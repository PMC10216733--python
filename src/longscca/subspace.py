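"""Label-guided deep subspace reconstruction.

Samples with the same diagnostic label are assumed to lie near a common
low-dimensional subspace.  An autoencoder maps samples to a latent code
z_i = f(x_i); a self-expression matrix C reconstructs each latent code as a
sparse combination of *same-label* codes (zero diagonal, zero across
labels); decoding the self-expressed codes g(C f(X)) yields a denoised view
that emphasizes the shared within-class structure.

The joint training loss is

    ||X - g(f(X))||_F^2 + lam_se ||f(X) - C f(X)||_F^2 + lam_l1 ||C||_1

minimized by full-batch gradient descent on the network parameters with a
backtracking step size (so the logged loss never increases) alternated with
exact lasso updates of C every few epochs.  The zero
diagonal and label-block support of C are structural: C is only ever
assembled from within-block lasso fits, never penalized into shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoLars

from .containers import OmicsMatrix

__all__ = [
    "SubspaceModel",
    "fit_self_expression",
    "train_reconstruction_network",
    "reconstruct",
    "reconstruct_linear",
]


@dataclass
class SubspaceModel:
    """A trained reconstruction network plus its self-expression matrix."""

    encoder_params: list  # [(W, b), ...]
    decoder_params: list
    self_expression: np.ndarray  # N x N, zero diagonal, label-block support
    arch: list
    train_log: list = field(default_factory=list)
    labels: np.ndarray | None = None
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def n_train_samples(self) -> int:
        return self.self_expression.shape[0]

    def encode(self, Xs: np.ndarray) -> np.ndarray:
        h = Xs
        for W, b in self.encoder_params:
            h = np.tanh(h @ W + b)
        return h

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = Z
        for W, b in self.decoder_params[:-1]:
            h = np.tanh(h @ W + b)
        W, b = self.decoder_params[-1]
        return h @ W + b

    def autoencode(self, view: OmicsMatrix) -> OmicsMatrix:
        """Plain autoencoder pass g(f(X)) without self-expression."""
        Xs = (view.values - self.mu) / self.sd
        out = self.decode(self.encode(Xs)) * self.sd + self.mu
        return OmicsMatrix(
            pd.DataFrame(out, index=view.sample_ids, columns=view.feature_names),
            view.labels,
        )


def fit_self_expression(latent: np.ndarray, labels, lam: float) -> np.ndarray:
    """Sparse self-expression coefficients within label blocks.

    For each sample i with label d, the column c_i minimizes
    (1/2)||z_i - Z_(d) c_i||^2 + lam ||c_i||_1 over coefficients supported
    on the other samples of label d (the self-coefficient is structurally
    zero).  Each column is an exact lasso solution (LARS path).
    """
    Z = np.asarray(latent, dtype=float)
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    labels = np.asarray(labels)
    C = np.zeros((n, n))
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise ValueError(f"degenerate input: label class {lab!r} has a single member")
        block = Z[idx]  # members x m
        for local_i, i in enumerate(idx):
            others = np.delete(idx, local_i)
            A = Z[others].T  # m x (members-1) dictionary
            if lam > 0:
                # LARS solves the lasso path exactly; with m latent
                # coordinates per code the active set stays small, so this
                # is much faster than coordinate descent here.
                # sklearn objective: (1/(2m))||y - Aw||^2 + alpha||w||_1
                # tiny deterministic jitter guards the LARS path against
                # exactly tied correlations (e.g. duplicated codes)
                model = LassoLars(
                    alpha=lam / m, fit_intercept=False, jitter=1e-10, random_state=0
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(A, Z[i])
                coef = model.coef_
            else:
                coef, *_ = np.linalg.lstsq(A, Z[i], rcond=None)
            C[i, others] = coef
        del block
    return C


def _init_params(sizes, rng):
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        params.append([rng.normal(0.0, scale, size=(fan_in, fan_out)), np.zeros(fan_out)])
    return params


def _forward(Xs, enc, dec):
    acts = [Xs]
    h = Xs
    for W, b in enc:
        h = np.tanh(h @ W + b)
        acts.append(h)
    Z = h
    for W, b in dec[:-1]:
        h = np.tanh(h @ W + b)
        acts.append(h)
    W, b = dec[-1]
    out = h @ W + b
    acts.append(out)
    return Z, out, acts


def _loss_and_grads(Xs, enc, dec, C, lam_se, lam_l1):
    n_enc = len(enc)
    Z, out, acts = _forward(Xs, enc, dec)
    resid = out - Xs
    R = Z - C @ Z
    loss = float((resid**2).sum()) + lam_se * float((R**2).sum()) + lam_l1 * float(
        np.abs(C).sum()
    )

    grads_enc = [[None, None] for _ in enc]
    grads_dec = [[None, None] for _ in dec]

    # backprop through decoder (last layer linear)
    delta = 2.0 * resid
    layers = enc + dec
    grads = grads_enc + grads_dec
    for li in range(len(layers) - 1, n_enc - 1, -1):
        W, _ = layers[li]
        a_in = acts[li]
        grads[li][0] = a_in.T @ delta
        grads[li][1] = delta.sum(axis=0)
        delta = delta @ W.T
        if li > n_enc:  # tanh on decoder hidden layers
            delta = delta * (1.0 - acts[li] ** 2)
    # inject self-expression gradient at the latent layer
    IC = R - C.T @ R  # (I - C)^T (Z - CZ)
    delta = (delta + 2.0 * lam_se * IC) * (1.0 - acts[n_enc] ** 2)
    for li in range(n_enc - 1, -1, -1):
        W, _ = layers[li]
        a_in = acts[li]
        grads[li][0] = a_in.T @ delta
        grads[li][1] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ W.T) * (1.0 - acts[li] ** 2)
    return loss, grads_enc, grads_dec


def train_reconstruction_network(
    view: OmicsMatrix,
    labels=None,
    arch: list | None = None,
    epochs: int = 500,
    lam_se: float = 1.0,
    lam_l1: float = 0.01,
    seed: int = 0,
    lr: float = 1e-3,
    c_update_every: int = 10,
) -> SubspaceModel:
    """Train the reconstruction network on one view.

    ``arch`` lists hidden layer sizes of the encoder (default [64, 32]);
    the decoder mirrors it.  C is refreshed by exact lasso every
    ``c_update_every`` epochs and once more after the final epoch.  With
    ``epochs=0`` the network stays at initialization and C stays zero.
    """
    if labels is None:
        if view.labels is None:
            raise ValueError("labels required (pass explicitly or attach to the view)")
        labels = view.labels.to_numpy()
    labels = np.asarray(labels)
    arch = list(arch) if arch is not None else [64, 32]
    if len(arch) < 1:
        raise ValueError("need at least one hidden layer")

    X = view.values
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    enc = _init_params([p] + arch, rng)
    dec = _init_params(list(reversed(arch)) + [p], rng)
    C = np.zeros((n, n))
    # lasso weight matching the joint loss: lam_se * ||.||^2 + lam_l1 * ||.||_1
    lam_lasso = lam_l1 / (2.0 * lam_se) if lam_se > 0 else lam_l1

    train_log: list[float] = []
    step = lr
    loss, ge, gd = _loss_and_grads(Xs, enc, dec, C, lam_se, lam_l1)
    for epoch in range(1, epochs + 1):
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        if c_update_every > 0 and epoch % c_update_every == 0:
            Z = SubspaceModel(enc, dec, C, arch).encode(Xs)
            C = fit_self_expression(Z, labels, lam_lasso)
            loss, ge, gd = _loss_and_grads(Xs, enc, dec, C, lam_se, lam_l1)
        accepted = False
        for _ in range(40):
            enc_new = [[W - step * gW, b - step * gb] for (W, b), (gW, gb) in zip(enc, ge)]
            dec_new = [[W - step * gW, b - step * gb] for (W, b), (gW, gb) in zip(dec, gd)]
            new_loss, ge_new, gd_new = _loss_and_grads(Xs, enc_new, dec_new, C, lam_se, lam_l1)
            if np.isfinite(new_loss) and new_loss <= loss:
                enc, dec = enc_new, dec_new
                loss, ge, gd = new_loss, ge_new, gd_new
                step = min(step * 1.1, lr * 100)
                accepted = True
                break
            step /= 2.0
        if not accepted:
            step = lr  # reset; parameters unchanged, loss flat
        train_log.append(loss)

    if epochs > 0:
        Z = SubspaceModel(enc, dec, C, arch).encode(Xs)
        C = fit_self_expression(Z, labels, lam_lasso)
        loss, _, _ = _loss_and_grads(Xs, enc, dec, C, lam_se, lam_l1)
        train_log.append(loss)

    return SubspaceModel(
        encoder_params=[tuple(x) for x in enc],
        decoder_params=[tuple(x) for x in dec],
        self_expression=C,
        arch=arch,
        train_log=train_log,
        labels=labels,
        mu=mu,
        sd=sd,
    )


def reconstruct_linear(view: OmicsMatrix, labels=None, lam: float = 0.01) -> OmicsMatrix:
    """Ablation: self-expression fit directly in input space, no network.

    Returns C X on the standardized view, mapped back to the original
    scale — the purely linear subspace reconstruction.
    """
    if labels is None:
        if view.labels is None:
            raise ValueError("labels required")
        labels = view.labels.to_numpy()
    X = view.values
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    C = fit_self_expression(Xs, np.asarray(labels), lam)
    out = (C @ Xs) * sd + mu
    return OmicsMatrix(
        pd.DataFrame(out, index=view.sample_ids, columns=view.feature_names),
        view.labels,
    )


def reconstruct(model: SubspaceModel, view: OmicsMatrix) -> OmicsMatrix:
    """Decode the self-expressed latent codes: g(C f(X)).

    The view must match the training view in both feature dimension and
    sample count (C couples the training samples).
    """
    X = view.values
    if X.shape[1] != model.mu.shape[0]:
        raise ValueError("feature dimension does not match the trained model")
    if X.shape[0] != model.n_train_samples:
        raise ValueError("sample count does not match the trained self-expression matrix")
    Xs = (X - model.mu) / model.sd
    Z = model.encode(Xs)
    out = model.decode(model.self_expression @ Z) * model.sd + model.mu
    return OmicsMatrix(
        pd.DataFrame(out, index=view.sample_ids, columns=view.feature_names),
        view.labels,
    )
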