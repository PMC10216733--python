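"""Experiment protocols: hyperparameter grid search, noise sweep, the full
reconstruction-hypergraph-CCA pipeline, regression of phenotypes on top
genes, and the reconstruction-vs-raw clustering comparison.

Every run is reproducible from its seed; pipeline runs can emit a
``run_manifest.json`` recording the configuration, the seed, and content
hashes of the input files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import BayesianRidge, LinearRegression, Ridge
from sklearn.model_selection import KFold

from .containers import LongitudinalPhenotype, OmicsMatrix
from .hypergraph import build_knn_hypergraph, laplacian
from .metrics import EvaluationReport, clustering_indices, r2_score, top_k_features
from .scca import CanonicalModel, PenaltyConfig, fit, fit_tgscca, score_ccc
from .simulate import SimulationConfig, generate_joint_longitudinal, train_test_split_41
from .subspace import reconstruct, train_reconstruction_network

__all__ = [
    "ExperimentConfig",
    "grid_search",
    "run_noise_sweep",
    "run_full_pipeline",
    "regression_eval",
    "clustering_comparison",
]

PAPER_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0)


@dataclass
class ExperimentConfig:
    """Configuration shared by the experiment protocols.

    The default tuning range for every penalty is {0.0001, 0.001, 0.01,
    0.1, 1}.  Sweeping five penalties independently costs 5^5 = 3125 fits
    per grid search; by default the hypergraph weights are tied
    (beta1 = beta2) and the phenotype structure weights are tied
    (lam2 = lamt), reducing the default sweep to 125 fits.  Set
    ``full_grid=True`` to sweep all five independently.
    """

    lam1_grid: tuple = PAPER_GRID
    lam2_grid: tuple = PAPER_GRID
    lamt_grid: tuple = PAPER_GRID
    beta1_grid: tuple = PAPER_GRID
    beta2_grid: tuple = PAPER_GRID
    full_grid: bool = False
    noise_levels: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    n_seeds: int = 10
    knn_k: int = 5
    cv_folds: int = 5
    selection: str = "cv"  # "cv" (k-fold held-out CCC) or "train" (train-set CCC)
    one_se_rule: bool = False  # pick the sparsest combo within 1 SE of the best CV score
    reconstruct: bool = True
    reconstruct_before_split: bool = True
    shared_y_laplacian: bool = False
    fused_norm: str = "l2"
    recon_arch: tuple = (64, 32)
    recon_epochs: int = 100
    recon_lam_se: float = 1.0
    recon_lam_l1: float = 0.01
    recon_c_update_every: int = 10
    max_iter: int = 100
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.selection not in ("cv", "train"):
            raise ValueError("selection must be 'cv' or 'train'")
        for name in ("lam1_grid", "lam2_grid", "lamt_grid", "beta1_grid", "beta2_grid"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} values must be >= 0")

    def penalty_combos(self, use_hypergraph: bool) -> list[dict]:
        """Enumerate the penalty grid as dicts of PenaltyConfig fields."""
        if self.full_grid:
            prod = itertools.product(
                self.lam1_grid,
                self.lam2_grid,
                self.lamt_grid,
                self.beta1_grid if use_hypergraph else (0.0,),
                self.beta2_grid if use_hypergraph else (0.0,),
            )
            return [
                dict(lam1=a, lam2=b, lamt=c, beta1=d, beta2=e) for a, b, c, d, e in prod
            ]
        prod = itertools.product(
            self.lam1_grid,
            self.lam2_grid,  # tied lam2 = lamt
            self.beta1_grid if use_hypergraph else (0.0,),  # tied beta1 = beta2
        )
        return [dict(lam1=a, lam2=b, lamt=b, beta1=d, beta2=d) for a, b, d in prod]

    def penalty_config(self, **kw) -> PenaltyConfig:
        return PenaltyConfig(
            max_iter=self.max_iter, tol=self.tol, fused_norm=self.fused_norm, **kw
        )


def _laplacians(X, Ys, k: int, shared: bool):
    """Sample-level hypergraph Laplacians for the gene view and each Y_t."""
    L1 = laplacian(build_knn_hypergraph(X, k=k))
    if shared:
        ymean = np.mean([np.asarray(y, dtype=float) for y in _arrays(Ys)], axis=0)
        L = laplacian(build_knn_hypergraph(ymean, k=k))
        L2s = [L] * len(_arrays(Ys))
    else:
        L2s = [laplacian(build_knn_hypergraph(y, k=k)) for y in _arrays(Ys)]
    return L1, L2s


def _arrays(Ys):
    if isinstance(Ys, LongitudinalPhenotype):
        return Ys.arrays()
    return [y.values if isinstance(y, OmicsMatrix) else np.asarray(y, dtype=float) for y in Ys]


def _values(X):
    return X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)


def _fit_with_laplacians(X, Ys, pcfg: PenaltyConfig, use_hypergraph: bool, cfg: ExperimentConfig):
    if use_hypergraph and (pcfg.beta1 > 0 or pcfg.beta2 > 0):
        L1, L2s = _laplacians(X, Ys, cfg.knn_k, cfg.shared_y_laplacian)
        return fit(X, Ys, L1, L2s, pcfg)
    if use_hypergraph:
        return fit(X, Ys, None, None, pcfg)
    return fit_tgscca(X, Ys, pcfg)


def grid_search(X, Ys, cfg: ExperimentConfig, use_hypergraph: bool = True, seed: int = 0):
    """Select penalties by grid search on the training views.

    With ``cfg.selection == "cv"`` each grid point is scored by k-fold
    cross-validation on the training split (mean held-out CCC across time
    points and folds; degenerate folds score as missing).  With
    ``"train"`` each grid point is fit once and scored by its training-set
    mean CCC.  Returns (best PenaltyConfig, score table).
    """
    X = _values(X)
    Ys = _arrays(Ys)
    n = X.shape[0]
    combos = cfg.penalty_combos(use_hypergraph)
    rows = []
    if cfg.selection == "cv":
        if n < cfg.cv_folds:
            raise ValueError("training set smaller than the number of CV folds")
        splits = list(KFold(cfg.cv_folds, shuffle=True, random_state=seed).split(X))
    for combo in combos:
        pcfg = cfg.penalty_config(**combo)
        if cfg.selection == "train":
            model = _fit_with_laplacians(X, Ys, pcfg, use_hypergraph, cfg)
            try:
                score = float(np.mean(score_ccc(model, X, Ys)))
            except ValueError:
                score = np.nan
        else:
            fold_scores = []
            for tr, te in splits:
                model = _fit_with_laplacians(
                    X[tr], [y[tr] for y in Ys], pcfg, use_hypergraph, cfg
                )
                try:
                    fold_scores.append(
                        float(np.mean(score_ccc(model, X[te], [y[te] for y in Ys])))
                    )
                except ValueError:
                    fold_scores.append(np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                score = float(np.nanmean(fold_scores)) if fold_scores else np.nan
                sem = (
                    float(np.nanstd(fold_scores) / np.sqrt(np.isfinite(fold_scores).sum()))
                    if np.isfinite(fold_scores).any()
                    else np.nan
                )
            rows.append({**combo, "score": score, "score_se": sem})
            continue
        rows.append({**combo, "score": score})
    table = pd.DataFrame(rows)
    if table["score"].notna().any():
        best_idx = int(table["score"].idxmax())
        if cfg.one_se_rule and cfg.selection == "cv":
            # flat CV curves: prefer the most penalized combo whose score is
            # within one standard error of the best (the glmnet-style rule)
            threshold = table.loc[best_idx, "score"] - table.loc[best_idx, "score_se"]
            ok = table[table["score"] >= threshold]
            keys = ["lam1", "lam2", "lamt", "beta1", "beta2"]
            best_idx = int(ok.sort_values(keys, ascending=False).index[0])
    else:
        best_idx = 0
    best = cfg.penalty_config(
        **{k: float(table.loc[best_idx, k]) for k in ("lam1", "lam2", "lamt", "beta1", "beta2")}
    )
    return best, table


def _reconstruct_views(gene: OmicsMatrix, pheno: LongitudinalPhenotype, cfg: ExperimentConfig, seed: int):
    """Deep-subspace reconstruct the gene view and all phenotype views.

    One model for the gene view; one shared model for the phenotype views,
    trained on the concatenation of time points with each sample-time pair
    keeping its subject's label.
    """
    gmodel = train_reconstruction_network(
        gene,
        arch=list(cfg.recon_arch),
        epochs=cfg.recon_epochs,
        lam_se=cfg.recon_lam_se,
        lam_l1=cfg.recon_lam_l1,
        seed=seed,
        c_update_every=cfg.recon_c_update_every,
    )
    gene_rec = reconstruct(gmodel, gene)

    T = pheno.n_timepoints
    n = len(pheno.sample_ids)
    stacked = pd.concat([v.data for v in pheno], axis=0, ignore_index=True)
    stacked.index = pd.Index(
        [f"{sid}@T{t + 1}" for t in range(T) for sid in pheno.sample_ids], name="sample_id"
    )
    labels = pd.concat([v.labels for v in pheno], ignore_index=True)
    labels.index = stacked.index
    big = OmicsMatrix(stacked, labels)
    pmodel = train_reconstruction_network(
        big,
        arch=list(cfg.recon_arch),
        epochs=cfg.recon_epochs,
        lam_se=cfg.recon_lam_se,
        lam_l1=cfg.recon_lam_l1,
        seed=seed + 1,
        c_update_every=cfg.recon_c_update_every,
    )
    big_rec = reconstruct(pmodel, big)
    views = []
    for t in range(T):
        chunk = big_rec.data.iloc[t * n : (t + 1) * n].copy()
        chunk.index = pheno.sample_ids
        views.append(OmicsMatrix(chunk, pheno[t].labels))
    return gene_rec, LongitudinalPhenotype(views)


def run_noise_sweep(cfg: ExperimentConfig, sim_config: SimulationConfig | None = None,
                    out_dir=None, base_seed: int = 0) -> pd.DataFrame:
    """Compare the hypergraph method and the baseline across noise levels.

    For every noise level sigma_e and seed: simulate, split 4:1, grid-search
    on the training split, refit, and record the test CCC of every time
    point for both algorithms under identical splits and grids.  Returns a
    tidy table (algorithm, noise, seed, time, ccc) and, when ``out_dir`` is
    given, writes ``noise_sweep.csv`` plus one line plot per noise level.
    """
    sim_config = sim_config or SimulationConfig()
    rows = []
    for noise in cfg.noise_levels:
        for s in range(cfg.n_seeds):
            seed = base_seed + 1000 * s
            sc = dataclasses.replace(sim_config, noise_sigma=float(noise), seed=seed)
            ds = generate_joint_longitudinal(sc)
            train, test = train_test_split_41(ds, seed=seed)
            gene_tr, pheno_tr = train.gene_view, train.pheno_views
            if cfg.reconstruct:
                gene_tr, pheno_tr = _reconstruct_views(gene_tr, pheno_tr, cfg, seed)
            for algorithm, use_hg in (("tgscca", False), ("ds-hbtgscca", True)):
                gtr = gene_tr if use_hg else train.gene_view
                ptr = pheno_tr if use_hg else train.pheno_views
                best, _ = grid_search(gtr, ptr, cfg, use_hypergraph=use_hg, seed=seed)
                model = _fit_with_laplacians(
                    _values(gtr), _arrays(ptr), best, use_hg, cfg
                )
                try:
                    cccs = score_ccc(model, test.gene_view, test.pheno_views)
                except ValueError:
                    cccs = [np.nan] * len(test.pheno_views)
                for t, val in enumerate(cccs, start=1):
                    rows.append(
                        {
                            "algorithm": algorithm,
                            "noise": float(noise),
                            "seed": seed,
                            "time": t,
                            "ccc": val,
                        }
                    )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "noise_sweep.csv", index=False)
        _plot_noise_sweep(table, out)
    return table


def _plot_noise_sweep(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for noise, sub in table.groupby("noise"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for algorithm, chunk in sub.groupby("algorithm"):
            mean = chunk.groupby("time")["ccc"].mean()
            ax.plot(mean.index, mean.values, marker="o", label=algorithm)
        ax.set_xlabel("time point")
        ax.set_ylabel("mean test CCC")
        ax.set_title(f"noise sigma_e = {noise:g}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"ccc_noise_{noise:g}.png", dpi=120)
        plt.close(fig)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_pipeline(
    gene_csv,
    pheno_csvs,
    labels_csv=None,
    cfg: ExperimentConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[EvaluationReport, CanonicalModel]:
    """The end-to-end protocol on CSV inputs.

    standardize -> deep-subspace reconstruct both views -> KNN hypergraph
    Laplacians on reconstructed data -> 4:1 split -> grid search -> final
    fit -> per-time test CCC plus top-10 phenotype and top-20 gene
    features.  With ``cfg.reconstruct=False`` the raw-data arm of the
    comparison is reproduced.
    """
    cfg = cfg or ExperimentConfig()
    labels = None
    if labels_csv is not None:
        lab = pd.read_csv(labels_csv)
        labels = pd.Series(lab.iloc[:, 1].to_numpy(), index=lab.iloc[:, 0].to_numpy())
    gene = OmicsMatrix.from_csv(gene_csv)
    if labels is not None:
        missing = gene.sample_ids.difference(labels.index)
        if len(missing):
            raise ValueError(f"samples without labels: {list(missing)[:5]}")
        gene.labels = labels.loc[gene.sample_ids]
    views = []
    for path in pheno_csvs:
        v = OmicsMatrix.from_csv(path)
        if not v.sample_ids.equals(gene.sample_ids):
            bad = v.sample_ids.symmetric_difference(gene.sample_ids)
            raise ValueError(f"sample-ID mismatch in {path}: {list(bad)[:5]}")
        v.labels = gene.labels
        views.append(v)
    pheno = LongitudinalPhenotype(views)

    if cfg.reconstruct and cfg.reconstruct_before_split:
        gene, pheno = _reconstruct_views(gene, pheno, cfg, seed)
    train_gene, test_gene = train_test_split_41(gene, seed=seed)
    train_pheno, test_pheno = train_test_split_41(pheno, seed=seed)
    if cfg.reconstruct and not cfg.reconstruct_before_split:
        train_gene, train_pheno = _reconstruct_views(train_gene, train_pheno, cfg, seed)
        test_gene, test_pheno = _reconstruct_views(test_gene, test_pheno, cfg, seed)

    best, table = grid_search(train_gene, train_pheno, cfg, use_hypergraph=True, seed=seed)
    model = _fit_with_laplacians(
        _values(train_gene), _arrays(train_pheno), best, True, cfg
    )
    model.gene_features = list(gene.feature_names)
    model.pheno_features = list(pheno.feature_names)

    try:
        cccs = score_ccc(model, test_gene, test_pheno)
    except ValueError:
        cccs = [float("nan")] * pheno.n_timepoints
    report = EvaluationReport(
        ccc_per_time=[float(c) for c in cccs],
        mean_ccc=float(np.nanmean(cccs)),
        top_features={
            "phenotype": top_k_features(
                np.linalg.norm(model.V, axis=1), pheno.feature_names,
                min(10, len(pheno.feature_names)),
            ),
            "gene": top_k_features(
                model.u, gene.feature_names, min(20, len(gene.feature_names))
            ),
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": dataclasses.asdict(cfg),
            "seed": seed,
            "selected_penalties": {
                k: getattr(best, k) for k in ("lam1", "lam2", "lamt", "beta1", "beta2")
            },
            "inputs": {
                str(gene_csv): _file_hash(gene_csv),
                **{str(p): _file_hash(p) for p in pheno_csvs},
            },
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        table.to_csv(out / "grid_search.csv", index=False)
        pd.DataFrame(
            {"time": range(1, len(report.ccc_per_time) + 1), "test_ccc": report.ccc_per_time}
        ).to_csv(out / "test_ccc.csv", index=False)
    return report, model


def regression_eval(
    gene_view: OmicsMatrix,
    pheno_view: OmicsMatrix,
    top_genes: list,
    method: str = "linear",
    seed: int = 0,
    ridge_alpha: float = 1.0,
) -> dict:
    """Regress each phenotype feature on the selected genes; report test R^2.

    ``method`` is one of {"bayes", "linear", "ridge"}; the split is the
    same 4:1 protocol used everywhere else.
    """
    if len(top_genes) < 1:
        raise ValueError("need at least one predictor gene")
    missing = [g for g in top_genes if g not in gene_view.feature_names]
    if missing:
        raise ValueError(f"genes not in the view: {missing[:5]}")
    makers = {
        "bayes": lambda: BayesianRidge(),
        "linear": lambda: LinearRegression(),
        "ridge": lambda: Ridge(alpha=ridge_alpha),
    }
    if method not in makers:
        raise ValueError(f"unknown method '{method}'")

    G = gene_view.data[list(top_genes)].to_numpy(dtype=float)
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = n // 5
    te, tr = np.sort(perm[:n_test]), np.sort(perm[n_test:])

    per_roi = {}
    for name in pheno_view.feature_names:
        y = pheno_view.data[name].to_numpy(dtype=float)
        reg = makers[method]()
        reg.fit(G[tr], y[tr])
        per_roi[name] = r2_score(y[te], reg.predict(G[te]))
    return {"per_roi": per_roi, "mean_r2": float(np.mean(list(per_roi.values())))}


def clustering_comparison(
    views: dict,
    labels,
    cfg: ExperimentConfig | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> pd.DataFrame:
    """Clustering quality with and without deep-subspace reconstruction.

    For every named view, k-means (k = number of label classes) is run with
    ``n_restarts`` distinct seeds on the raw data and on the reconstructed
    data; six indices (silhouette, pair-counting F-score/precision/recall,
    NMI, adjusted Rand) are reported as mean and SD over the restarts.
    With ``cfg.reconstruct=False`` both arms see identical data.
    """
    cfg = cfg or ExperimentConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    rows = []
    for view_name, view in views.items():
        if not isinstance(view, OmicsMatrix):
            view = OmicsMatrix(pd.DataFrame(np.asarray(view, dtype=float)))
        if view.labels is None:
            view = OmicsMatrix(view.data, pd.Series(labels, index=view.sample_ids))
        arms = {"raw": view}
        if cfg.reconstruct:
            smodel = train_reconstruction_network(
                view,
                arch=list(cfg.recon_arch),
                epochs=cfg.recon_epochs,
                lam_se=cfg.recon_lam_se,
                lam_l1=cfg.recon_lam_l1,
                seed=seed,
                c_update_every=cfg.recon_c_update_every,
            )
            arms["reconstructed"] = reconstruct(smodel, view)
        else:
            arms["reconstructed"] = view
        for arm, data in arms.items():
            X = data.values
            scores: dict[str, list] = {}
            for r in range(n_restarts):
                km = KMeans(n_clusters=len(classes), n_init=1, random_state=seed + r)
                pred = km.fit_predict(X)
                if len(np.unique(pred)) < 2:
                    continue
                idx = clustering_indices(X, pred, labels)
                for key in ("silhouette", "f_score", "precision", "recall", "nmi", "ari"):
                    scores.setdefault(key, []).append(idx[key])
            for key, vals in scores.items():
                rows.append(
                    {
                        "view": view_name,
                        "arm": arm,
                        "index": key,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals)),
                    }
                )
    return pd.DataFrame(rows)
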