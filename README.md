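# longscca

Sparse canonical correlation analysis for **longitudinal imaging
genetics**: given one static omics view (gene expression, samples × genes)
and a sequence of phenotype views measured over time (e.g. gray-matter
volume in 90 brain regions at T scan dates), `longscca` finds a sparse
gene weight vector **u** and time-indexed region weight vectors
**V = [v₁ … v_T]** whose projections are maximally correlated, while

* an **L1** penalty selects genes,
* an **L2,1** penalty selects the same regions across time,
* a **group-fused** penalty keeps consecutive time points' weights close,
* and **KNN hypergraph Laplacian** penalties keep the projected sample
  scores smooth over each view's high-order neighborhood structure.

The fitted objective (minimized under ‖Xu‖ ≤ 1, ‖Y_t v_t‖ ≤ 1) is

```
− Σ_t uᵀXᵀY_t v_t + λ1‖u‖₁ + λ2‖V‖₂,₁ + λt Σ_t ‖v_{t+1} − v_t‖₂
  + β1 (Xu)ᵀL₁(Xu) + β2 Σ_t (Y_t v_t)ᵀL₂ₜ(Y_t v_t)
```

With β1 = β2 = 0 this is the temporally-constrained group-sparse CCA
baseline (`fit_tgscca`). The full method additionally runs a **label-guided
deep subspace reconstruction** first: an autoencoder plus a zero-diagonal,
label-blocked self-expression matrix denoise each view toward its
within-diagnosis subspace structure before the hypergraphs and the
canonical model are built. Performance is reported as the canonical
correlation coefficient CCC_t = corr(Xu, Y_t v_t) per time point.

The package is aimed at methods researchers in imaging genetics /
multi-omics integration: it ships a complete latent-factor simulator for
coupled two-view longitudinal data, so every component can be exercised
and validated without restricted clinical data.

## Worked example

Simulate the default protocol (n=200 samples, 450 genes, 4 time points of
90 regions, half the columns of each view carrying a shared latent
signal), split 4:1, fit the baseline, and evaluate on the held-out fifth:

```python
import numpy as np
import longscca as L
from longscca.scca import PenaltyConfig, fit_tgscca, score_ccc
from longscca.metrics import support_recovery

cfg = L.SimulationConfig(n_samples=200, p_pheno=90, q_gene=450,
                         noise_sigma=1.0, seed=42)
ds = L.generate_joint_longitudinal(cfg)
train, test = L.train_test_split_41(ds, seed=42)
model = fit_tgscca(train.gene_view.values,
                   [v.values for v in train.pheno_views],
                   PenaltyConfig(lam1=1.0, lam2=0.01, lamt=0.01))
cccs = score_ccc(model, test.gene_view.values,
                 [v.values for v in test.pheno_views])
print([round(c, 3) for c in cccs])
print(support_recovery(model.u, ds.true_beta))
```

prints

```
[0.971, 0.971, 0.971, 0.968]
(1.0, 1.0, 1.0)
```

— the held-out canonical correlation is ≈0.97 at every time point (the
shared latent factor is strong at noise σ=1 and decays slightly by T4 as
temporal drift accumulates), and the nonzero entries of **u** recover the
planted 225 signal genes exactly (precision = recall = F1 = 1).

## Command line

```bash
longscca simulate --out data/ --seed 42          # write CSV views + truth.json
longscca pipeline data/gene_expression.csv data/phenotype_T*.csv \
         --labels data/labels.csv --out run/ --seed 42
longscca noise-sweep --out sweep/ --seed 42
```

`pipeline` runs reconstruction → hypergraph Laplacians → 4:1 split →
grid search over {0.0001, 0.001, 0.01, 0.1, 1} → final fit, and writes
per-time test CCCs, the top-10 regions and top-20 genes, the grid table,
and a `run_manifest.json` with config, seed, and input hashes. Other
subcommands: `reconstruct`, `hypergraph`, `fit`, `regress`,
`cluster-compare`.

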