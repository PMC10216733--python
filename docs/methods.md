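# Methods

## Problem setting

`longscca` estimates sparse associations between a static gene-expression
view and a longitudinal imaging phenotype. The data are a matrix
X ∈ R^{n×q} (n subjects, q genes) and T phenotype matrices
Y_t ∈ R^{n×p} (p regions of interest, one matrix per scan date), plus a
per-subject diagnostic label. The estimand is a gene weight vector
u ∈ R^q and a time-indexed ROI weight matrix V = [v_1 … v_T] ∈ R^{p×T}
such that the projected scores Xu and Y_t v_t are maximally correlated,
with u sparse, the rows of V jointly sparse, and the columns of V varying
smoothly in time.

## The canonical model

The fitted objective (minimization form) is

    f(u, V) = − Σ_t uᵀXᵀY_t v_t
              + λ1 ‖u‖₁  +  λ2 ‖V‖₂,₁  +  λt Σ_{t<T} ‖v_{t+1} − v_t‖₂
              + β1 (Xu)ᵀ L₁ (Xu)  +  β2 Σ_t (Y_t v_t)ᵀ L₂ₜ (Y_t v_t)

subject to ‖Xu‖₂ ≤ 1 and ‖Y_t v_t‖₂ ≤ 1. The first term rewards
cross-view correlation; the L1 term selects genes; the L2,1 term selects
ROIs consistently across time; the group-fused chain couples consecutive
time points; and the hypergraph quadratics smooth the projected sample
scores over the KNN hypergraph Laplacians of each view. Setting
β1 = β2 = 0 gives the temporally-constrained group-sparse CCA baseline
(`fit_tgscca`). The reported performance index is the canonical
correlation coefficient CCC_t = corr(Xu, Y_t v_t), which is invariant to
the scale of u and v_t.

The sign convention matters: the correlation term is *negated* and the
hypergraph quadratics are *added* in the minimization, so the optimizer
rewards correlation and penalizes roughness. The fused difference uses
the Euclidean norm per time-pair (group fused); an elementwise L1 variant
is available via `PenaltyConfig(fused_norm="l1")`.

## Optimization

Alternating block minimization over u and V. Each block handles its scale
constraint through a Lagrangian surrogate — the smooth part gains
(1/2)‖Xu‖² (resp. (1/2)‖Y_t v_t‖²) — solved by FISTA with the proximal
operator of the nonsmooth part, followed by rescaling into the feasible
set. The composite prox for the V block (row-wise group soft-threshold
for L2,1, then cyclic pairwise proximal passes for the fused chain, 20
cycles or 1e-8 change) is approximate, so every block update passes
through a monotone safeguard: among {previous iterate, feasible solution,
boundary-scaled solution, zero} the candidate with the lowest block
objective is kept. The recorded objective trace is therefore
non-increasing by construction, and exact null conditions
(‖c‖_∞ ≤ λ1 ⇒ u = 0; max row norm of the linear term ≤ λ2 ⇒ V = 0) are
applied analytically so null solutions are exact zeros rather than
numerically small.

**Covariance surrogate.** The quadratic in the surrogate uses the full
Gram matrix XᵀX when n ≥ 3× the block's feature count and its diagonal
otherwise (`PenaltyConfig.cov = "auto"`, overridable to `"full"` or
`"diag"`). The full Gram makes the penalty-free, single-time fit coincide
with classical CCA (alternating u = (XᵀX)⁻¹XᵀYv); the diagonal Gram is
the standard high-dimensional sparse-CCA surrogate — whitening through a
near-singular covariance amplifies noise directions and, in our
simulations at n=100/q=60, roughly halves support-recovery F1.

**Standardization.** Inside `fit`, columns are centered and scaled to
unit Euclidean norm. Cross-view gradient entries are then sums of Pearson
correlations (bounded by T), which is what makes the tuning range
{0.0001, 0.001, 0.01, 0.1, 1} span null-to-dense solutions. Constant
columns are kept (with a warning) and receive exactly zero weight. At
return, u is rescaled so ‖Xu‖ = 1 and V by a *common* factor so
max_t ‖Y_t v_t‖ = 1: a per-time rescale would destroy the fused structure
(columns driven equal by λt would be un-fused by unequal factors), and
CCC is unaffected either way.

**Schedule.** Outer loop: at most 100 iterations, stopping when the
relative objective change drops below 1e-5. Inner FISTA: 200 iterations,
tolerance 1e-8. Initialization is the rank-1 SVD of XᵀȲ with Ȳ the
time-mean phenotype view; every v_t starts at the shared right singular
vector, which is exactly fused and therefore a good starting point for
the temporal penalty.

## Hypergraphs

Vertices are samples. Each sample spawns one hyperedge containing itself
and its k nearest neighbors (Euclidean by default, any scipy metric
accepted), so the incidence matrix H is N×N with column sums k+1; ties
are broken by ascending sample index, making duplicated rows
deterministic. Default hyperedge weight is 1; a heat-kernel weight
w(e) = Σ_{v∈e} exp(−d(v, centroid)²/σ̄²), σ̄ = mean pairwise distance, is
available. With vertex degrees d(v) = Σ_e w(e)H(v,e) and edge degrees
δ(e) = Σ_v H(v,e), the normalized Laplacian is

    L = I − D_v^{−1/2} H W D_e^{−1} Hᵀ D_v^{−1/2},

symmetric and PSD with L·D_v^{1/2}1 = 0; the penalty xᵀLx is small when
a per-sample score x is smooth over hyperedges. k defaults to 5 (logged
by every experiment); with a few hundred samples the resulting
neighborhoods are local without fragmenting the graph. One Laplacian is
built per phenotype time point; `shared_y_laplacian` builds a single one
from the time-averaged phenotype instead.

## Deep subspace reconstruction

Samples with the same diagnosis are modeled as lying near a common
low-dimensional subspace. An autoencoder f/g (default encoder
p→64→32 with tanh, mirrored decoder, linear output) and a self-expression
matrix C are trained jointly on

    ‖X − g(f(X))‖²_F + λ_se ‖f(X) − C f(X)‖²_F + λ_l1 ‖C‖₁

with C constrained to zero diagonal and zero across label blocks. Both
constraints are structural: C is assembled only from within-block lasso
fits (exact LARS solutions) that exclude the sample itself, never relaxed
into a penalty. Network parameters take full-batch gradient steps with a
backtracking step size, so the logged loss is non-increasing; C is
refreshed every 10 epochs (configurable) and once after the last epoch.
The reconstructed view is g(C·f(X)) — each latent code replaced by its
sparse same-label combination, then decoded — which denoises toward the
shared within-class structure. The T phenotype time points share one
model trained on their concatenation, each sample–time pair keeping its
subject's label; the gene view gets its own model.

Defaults: λ_se = 1, λ_l1 = 0.01, learning rate 1e-3, 500 epochs. The
experiment protocols scale this down (architecture (16, 8), 40–100
epochs, C refresh every 10–20 epochs) for the simulated problem sizes,
where feature counts are 20–60 and larger latent spaces than the data
dimension would be meaningless.

A purely linear ablation (`reconstruct_linear`, CLI `--linear-subspace`)
fits the same label-blocked self-expression directly in input space and
returns C·X, isolating what the nonlinear encoder adds.

Reconstruction is applied before the train/test split by default
(`reconstruct_before_split`), mirroring a workflow in which the denoised
views are the analysis object; setting it to False reconstructs the two
splits separately, avoiding any information flow from test to train at
the cost of a test-set self-expression fitted on 20% of the samples.

## Synthetic data

`generate_joint_longitudinal` draws a latent severity ε_i ~ N(0, σ_ε²)
per sample. A planted half of the phenotype columns (evenly spread,
deterministic given the fraction) equals ε·α_j + e and a planted half of
the gene columns equals ε·β_j + e, with e ~ N(0, σ_e²) i.i.d.; the other
columns are pure noise and carry exactly zero true weight. Nonzero
weights are drawn from U(−1,−0.5) ∪ U(0.5,1) (sign Bernoulli(1/2),
magnitude uniform), so no planted effect is vanishingly small. Later
phenotype time points drift: Y_{t+1} = Y_t + Δ, Δ_ij ~ N(0, 0.1) — the
drift parameter is a variance (drift_sigma = √0.1), and noise is *not*
redrawn per time point, so signal decays only through drift accumulation.
Defaults: n=200, p=90, q=450, T=4, σ_ε=1, σ_e=1, half the columns
correlated in each view. σ_ε, the correlated fractions, and the labels
are free choices of this generator: labels are a median split of ε
(a two-group "severity" diagnosis), which gives the label-guided
reconstruction stage a meaningful grouping without changing the
statistical model of the views.

What the generator does *not* emulate: spatial autocorrelation between
ROIs, linkage structure between genes, heavy-tailed measurement noise,
site effects. Passing tests therefore show correctness of the estimator
under the stated latent-factor model, not robustness to real sMRI or
expression artifacts.

`generate_multisubspace` draws one orthonormal basis per class (QR of a
Gaussian matrix) and emits Gaussian coefficient combinations plus
isotropic noise — the regime the self-expression model is exact for.

## Evaluation protocols

* **Split**: a single unstratified 4:1 random partition applied to every
  view with identical indices (n=200 → 160/40).
* **Grid search**: every penalty swept over {0.0001, 0.001, 0.01, 0.1, 1};
  by default β1=β2 and λ2=λt are tied (125 combinations; `full_grid`
  expands to 3125). Scoring is 5-fold CV on the training split by mean
  held-out CCC across time points (degenerate folds score as missing); a
  `selection="train"` variant scores the training-set CCC instead. With
  `one_se_rule=True` the sparsest combination within one standard error of
  the best CV score is selected (the glmnet convention) — the CV curve is
  often flat in λ1 when the signal features are strongly inter-correlated,
  and the 1-SE rule resolves that flatness toward parsimony; the support
  recovery evaluation uses it.
* **Noise sweep**: σ_e ∈ {1..5}, both algorithms under identical splits
  and grids, per-time test CCC, tidy CSV plus one line plot per noise
  level.
* **Regression check**: each ROI regressed on a chosen top-gene set with
  linear, ridge, or Bayesian ridge regression; test R² = 1 − MSE/Var with
  population (divide-by-n) moments in both numerator and denominator.
* **Clustering comparison**: k-means (k = number of classes, 20 restarts)
  on raw vs reconstructed views; silhouette plus pair-counting
  F/precision/recall, NMI (arithmetic normalization), and adjusted Rand,
  as mean ± SD over restarts.

## Numerical choices and degenerate inputs

* Feature-ranking ties break by feature name; KNN distance ties break by
  sample index; support threshold |w| > 1e-8.
* Zero-variance projections raise an "undefined metric" error rather than
  returning NaN; grid-search folds hitting it are scored as missing.
* Rank-deficient direct solves use a relative ridge of 1e-10.
* An all-zero (u, V) solution is flagged in `model.diagnostics`, not
  raised.
* The acceptance script scales problem sizes down (n=100, p=30, q=60,
  5–10 seeds per statistic) — chosen so each statistic is stable to the
  tolerances asserted while the full run stays desk-scale.

## Known limitations

* The self-expression matrix ties the model to its training samples;
  `reconstruct` only applies to the same sample set (by design — C has
  one row per training sample).
* The V-block prox is approximate (alternating instead of exact composite
  prox); the monotone safeguard guarantees descent but convergence to the
  exact block minimizer is not guaranteed at pathological penalty
  combinations.
* CV-based model selection on strongly correlated features selects an
  arbitrary representative among near-duplicates; support recovery is
  judged against planted masks only in simulation.
* No GPU path; all sizes used here train in seconds-to-minutes on one
  CPU core.
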