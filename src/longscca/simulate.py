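"""Synthetic data generators.

Two families of datasets are produced:

* Coupled two-view longitudinal data: a static gene-expression view ``X``
  and T drifting phenotype views ``Y_1..Y_T`` share a scalar latent factor
  per sample, so that a planted subset of columns in each view is
  correlated across views.  This is the testbed for the sparse CCA solver.

* Multi-subspace labeled data: each class lives on its own low-dimensional
  linear subspace of the ambient space, the regime the label-guided
  self-expression reconstruction is designed for.

The coupled generator follows a latent-factor model: a per-sample latent
severity eps ~ N(0, sigma_eps^2); each *correlated* phenotype column j of
the baseline view is eps * alpha_j + e and each *correlated* gene column j
is eps * beta_j + e, with e ~ N(0, sigma_e^2) i.i.d. noise; uncorrelated
columns are pure noise.  Later phenotype time points drift by an additive
Gaussian increment: Y_{t+1} = Y_t + dv, dv_ij ~ N(0, drift_sigma^2).
Weight magnitudes are drawn from the signed uniform mixture
U(-1,-0.5) | U(0.5,1) so no planted weight is vanishingly small.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LongitudinalPhenotype, OmicsMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sample_signed_uniform",
    "generate_joint_longitudinal",
    "generate_multisubspace",
    "train_test_split_41",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the coupled longitudinal simulation.

    Defaults give n=200 samples, p=90 phenotype features (ROIs), q=450 gene
    features, T=4 time points, drift variance 0.1, unit latent and noise
    scales, and half of the columns of each view carrying signal.
    """

    n_samples: int = 200
    p_pheno: int = 90
    q_gene: int = 450
    n_timepoints: int = 4
    noise_sigma: float = 1.0
    latent_sigma: float = 1.0
    frac_correlated_pheno: float = 0.5
    frac_correlated_gene: float = 0.5
    drift_sigma: float = float(np.sqrt(0.1))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "p_pheno", "q_gene", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noise_sigma", "latent_sigma", "drift_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_correlated_pheno", "frac_correlated_gene"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """A generated two-view dataset plus its ground truth.

    ``true_alpha`` (length p) and ``true_beta`` (length q) are the planted
    weight vectors; entries outside the boolean masks are exactly zero.
    ``latent`` is the shared per-sample factor.
    """

    gene_view: OmicsMatrix
    pheno_views: LongitudinalPhenotype
    true_alpha: np.ndarray
    true_beta: np.ndarray
    latent: np.ndarray
    pheno_mask: np.ndarray
    gene_mask: np.ndarray
    config: SimulationConfig


def sample_signed_uniform(k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k values from the mixture U(-1,-0.5) union U(0.5,1).

    Sign is Bernoulli(1/2); magnitude is Uniform(0.5, 1). Mean 0,
    mean absolute value 0.75.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mag = rng.uniform(0.5, 1.0, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    return sign * mag


def _spread_mask(length: int, n_true: int) -> np.ndarray:
    """Deterministic mask with n_true evenly spread True entries."""
    mask = np.zeros(length, dtype=bool)
    if n_true > 0:
        idx = np.linspace(0, length - 1, n_true).round().astype(int)
        mask[np.unique(idx)] = True
        # rounding collisions: fill from the front
        short = n_true - mask.sum()
        if short > 0:
            mask[np.flatnonzero(~mask)[:short]] = True
    return mask


def generate_joint_longitudinal(config: SimulationConfig) -> SimulatedDataset:
    """Generate the coupled gene / longitudinal-phenotype dataset.

    Fully reproducible from ``config.seed``.  Labels (attached to every
    view) are a median split of the latent factor, serving as a synthetic
    two-group diagnosis for the label-guided reconstruction stage.
    """
    rng = np.random.default_rng(config.seed)
    n, p, q, T = (
        config.n_samples,
        config.p_pheno,
        config.q_gene,
        config.n_timepoints,
    )

    pheno_mask = _spread_mask(p, int(round(config.frac_correlated_pheno * p)))
    gene_mask = _spread_mask(q, int(round(config.frac_correlated_gene * q)))

    alpha = np.zeros(p)
    beta = np.zeros(q)
    if pheno_mask.any():
        alpha[pheno_mask] = sample_signed_uniform(int(pheno_mask.sum()), rng)
    if gene_mask.any():
        beta[gene_mask] = sample_signed_uniform(int(gene_mask.sum()), rng)

    eps = rng.normal(0.0, config.latent_sigma, size=n)

    gene = rng.normal(0.0, config.noise_sigma, size=(n, q))
    gene[:, gene_mask] += np.outer(eps, beta[gene_mask])

    y1 = rng.normal(0.0, config.noise_sigma, size=(n, p))
    y1[:, pheno_mask] += np.outer(eps, alpha[pheno_mask])

    pheno = [y1]
    for _ in range(T - 1):
        drift = rng.normal(0.0, config.drift_sigma, size=(n, p))
        pheno.append(pheno[-1] + drift)

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    gene_names = pd.Index([f"GENE_{j:04d}" for j in range(q)])
    roi_names = pd.Index([f"ROI_{j:03d}" for j in range(p)])
    labels = pd.Series(
        np.where(eps >= np.median(eps), "high", "low"), index=sample_ids
    )

    gene_view = OmicsMatrix(pd.DataFrame(gene, index=sample_ids, columns=gene_names), labels)
    pheno_views = LongitudinalPhenotype(
        [
            OmicsMatrix(pd.DataFrame(y, index=sample_ids, columns=roi_names), labels)
            for y in pheno
        ]
    )
    return SimulatedDataset(
        gene_view=gene_view,
        pheno_views=pheno_views,
        true_alpha=alpha,
        true_beta=beta,
        latent=eps,
        pheno_mask=pheno_mask,
        gene_mask=gene_mask,
        config=config,
    )


def generate_multisubspace(
    n_per_class: int,
    ambient_dim: int,
    subspace_dim: int,
    n_classes: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> OmicsMatrix:
    """Labeled samples drawn from one low-dimensional subspace per class.

    Per class an orthonormal basis of ``subspace_dim`` directions is drawn
    (QR of a Gaussian matrix); samples are random combinations of the basis
    plus isotropic Gaussian noise.
    """
    if subspace_dim >= ambient_dim:
        raise ValueError("subspace_dim must be < ambient_dim")
    if n_per_class < 1 or n_classes < 1:
        raise ValueError("n_per_class and n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c in range(n_classes):
        basis, _ = np.linalg.qr(rng.normal(size=(ambient_dim, subspace_dim)))
        coeff = rng.normal(size=(n_per_class, subspace_dim))
        blocks.append(coeff @ basis.T)
        labels.extend([f"class_{c}"] * n_per_class)
    data = np.vstack(blocks)
    # noise drawn last: the planted structure at a given seed is shared
    # across noise levels
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    ids = pd.Index([f"S{i:04d}" for i in range(data.shape[0])], name="sample_id")
    cols = pd.Index([f"F_{j:03d}" for j in range(ambient_dim)])
    return OmicsMatrix(pd.DataFrame(data, index=ids, columns=cols), pd.Series(labels, index=ids))


def train_test_split_41(dataset, seed: int = 0):
    """Split samples 4:1 (80% train / 20% test), same indices in every view.

    Accepts a :class:`SimulatedDataset`, an :class:`OmicsMatrix`, or a
    :class:`LongitudinalPhenotype`; returns a (train, test) pair of the same
    type.  A single unstratified random partition, deterministic per seed.
    """
    if isinstance(dataset, SimulatedDataset):
        n = dataset.gene_view.n_samples
    elif isinstance(dataset, (OmicsMatrix, LongitudinalPhenotype)):
        n = len(dataset.sample_ids)
    else:
        raise TypeError("unsupported input type")
    if n < 5:
        raise ValueError("need at least 5 samples for a 4:1 split")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = n // 5
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])

    def take(obj, idx):
        if isinstance(obj, SimulatedDataset):
            return SimulatedDataset(
                gene_view=obj.gene_view.subset(idx),
                pheno_views=obj.pheno_views.subset(idx),
                true_alpha=obj.true_alpha,
                true_beta=obj.true_beta,
                latent=obj.latent[idx],
                pheno_mask=obj.pheno_mask,
                gene_mask=obj.gene_mask,
                config=obj.config,
            )
        return obj.subset(idx)

    return take(dataset, train_idx), take(dataset, test_idx)


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    """Write one CSV per view plus truth.json (weights, masks, config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.gene_view.to_csv(out / "gene_expression.csv")
    for t, view in enumerate(dataset.pheno_views, start=1):
        view.to_csv(out / f"phenotype_T{t}.csv")
    if dataset.gene_view.labels is not None:
        lab = dataset.gene_view.labels.rename("label").rename_axis("sample_id")
        lab.reset_index().to_csv(out / "labels.csv", index=False)
    truth = {
        "alpha": dataset.true_alpha.tolist(),
        "beta": dataset.true_beta.tolist(),
        "latent": dataset.latent.tolist(),
        "pheno_mask": dataset.pheno_mask.astype(int).tolist(),
        "gene_mask": dataset.gene_mask.astype(int).tolist(),
        "config": dataclasses.asdict(dataset.config),
    }
    (out / "truth.json").write_text(json.dumps(truth))
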