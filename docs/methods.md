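# Methods

## Model and estimator

Centered expression at time `t ∈ [0,1]` is modeled as `N_p(0, Σ(t))` with a
smoothly varying precision matrix `Ω(t) = Σ(t)⁻¹`; the network at `t` is the
off-diagonal support of `Ω(t)`. At grid point `t_k` the estimator minimizes,
over the neighborhood `N_{k,d} = {i : |t_i − t_k| ≤ d}`,

    (1/|N|) Σ_{i∈N} [ tr(Ω(t_i) Σ̂(t_i)) − log|Ω(t_i)| ]
      + λ Σ_{u≠v} sqrt( Σ_{i∈N} Ω_uv(t_i)² ),

and reports the neighborhood solution's matrix at the center index. The
penalty sum runs over ordered pairs; since all iterates are symmetric this
is an effective weight of 2λ per unordered pair and only rescales λ.
Consequences used throughout:

- **Empty-graph threshold.** The all-diagonal candidate is optimal exactly
  when `λ ≥ max_{u≠v} ‖{Σ̂_uv(t_i)}_{i∈N}‖₂ / |N|` (KKT stationarity);
  `lambda_max` computes this bound.
- **Blockwise screening.** Variables split into connected components of the
  graph with edge (u,v) iff `sqrt(Σ_i Σ̂_uv(t_i)²)/|N| > λ`; components are
  fitted independently and assembled block-diagonally. Equality of supports
  with the full solve is verified by test rather than taken on authority.
- **Special cases.** `d = 0` is an independent graphical lasso per grid
  point ("kernel"); `d = 1` with one shared λ groups every edge across the
  whole grid, so all supports coincide ("invar").

### Correlation-scale fitting

Kernel covariances are converted to correlation matrices before fitting
(`standardize=True`), and fitted precisions are mapped back by
`Ω = D^{−1/2} Ω_std D^{−1/2}` (identical support). A single λ then acts
uniformly across variable pairs regardless of their variances; cross-
validation trains and scores on the same correlation scale. Pass
`standardize=False` to work on raw covariances.

### Solver

ADMM with scaled dual variables: the likelihood step is an
eigendecomposition update per neighborhood time, the penalty step a
groupwise soft-threshold (threshold `λ/ρ` on the per-pair neighborhood
norm). Defaults: ρ starts at 1 and adapts by ×2/÷2 when primal and dual
residuals diverge by more than 10×; stop when both RMS residuals fall below
1e-5; at most 500 iterations (a `ConvergenceError` carrying the residuals is
raised otherwise). The returned matrices are the positive-definite
likelihood iterates masked by the exact sparsity pattern of the penalty
iterate. Edge supports are read at |entry| > 1e-6.

`refit_support` (the constrained MLE used by CV scoring and after cv.vote)
reuses the same ADMM core with the penalty step replaced by projection onto
the fixed sparsity pattern; full support reproduces `Σ̂⁻¹`, empty support
`diag(1/Σ̂_uu)`.

The pseudo-likelihood mode replaces the joint likelihood with kernel-
weighted nodewise regressions solved by FISTA; the coefficients
`β_uv(t_i)` and `β_vu(t_i)` across the neighborhood form one penalty group
with weight `sqrt(2)·λ` (so a symmetric solution matches the likelihood
penalty's scale), making edge selection symmetric by construction. Entries
are refit on the selected support at the center covariance.

## Kernel smoothing and centering

The default kernel is Epanechnikov (`0.75(1−u²)` on |u|<1): compact support
keeps estimates local and makes several exact identities testable; a
Gaussian kernel is available where smoother pooling is preferred. Weights
are normalized to sum to one at each evaluation time. Observations are
centered by subtracting the kernel mean at each sample's own time, with the
same weights as the covariance smoother. With a compact kernel and `h`
below the grid spacing (0.125 for nine points), the kernel-weighted mean of
the centered data is exactly zero at every grid point; for larger `h` a
residual of the order of the trend curvature over the bandwidth remains.
This is the behavior of plain kernel-mean subtraction and is intentional.

## Cross-validation and consensus

Grid point `j` belongs to fold `j mod K`; for nine points and K=3 the
validation sets are {1,4,7}, {2,5,8}, {3,6,9} (1-based). For a candidate
`(h, d, λ)` the model is fitted on training-fold covariances, the selected
support refit by constrained MLE, and scored against the held-out fold's
kernel covariance by `tr(Ω_rf Σ̂_val) − log|Ω_rf|`, summed over folds.
λ is searched from sparse to dense within each `(h, d)` cell, and the
descent stops once any fold's edge count exceeds `8p` (configurable
multiplier). `(d_k, λ_k)` are selected per grid point; `h` is shared,
chosen by the total score over all grid points (the per-point alternative
is a one-line change but couples poorly with the shared centering scale).
Ties break toward larger λ, then larger d, then larger h — prefer sparser,
smoother graphs. K=1 is refused: the validation score is undefined.

With a compactly supported kernel, a training or validation subset can have
zero kernel mass at some grid point (K=3 removes every third point, and
`h < 0.25` cannot bridge two removed neighbors). The deterministic fallback
is a uniform average over the subset's nearest-in-time samples.

cv.vote retains edges present in at least a threshold fraction (default
0.8) of the fold models — with K=3 that is the intersection — and the final
matrices are constrained-MLE refits of the consensus support on the
full-data covariance. The vote can only remove edges relative to any single
fold fit, so false positives never increase; the cost is recall.

## Synthetic data

`generate_graph_trajectory` builds ground truth for testing and power
analysis: `base_edges` persistent edges with constant weights, plus
`n_changing` transient edges whose weight follows a raised-cosine bump over
a random grid-aligned sub-interval, so each edge's active period is one
contiguous run of grid points. Weights are drawn uniformly from
[0.2, 0.4] in magnitude with random sign; positive definiteness is enforced
by setting the diagonal to the row-wise absolute off-diagonal sum plus one,
which preserves the intended support exactly. The default grid is nine
equally spaced points, mirroring nine age periods, and sampling uses
per-grid-point child RNGs derived from one root seed, so draws at one grid
point do not depend on other points' replicate counts.

What this emulates: zero-mean Gaussian replicates per age group with a
smoothly rewiring conditional-dependence structure. What it does not:
microarray noise, probe effects, surrogate-variable structure, unequal
group sizes, or any claim about the true smoothness of cortical gene
networks. Passing tests certify the estimator and the downstream analysis
under the stated model, not performance on raw array data.

### Statistical power at the default study size

Diagonal dominance bounds the partial correlations of true edges at roughly
`w / (1 + Σ|w_row|)` ≈ 0.13–0.18 for weights in [0.2, 0.4]. With 30
replicates per grid point the kernel/neighborhood pooling raises the
effective sample size to at most a few hundred, so edge z-scores sit near
2–3 against ~180 candidate pairs: support recovery is intrinsically
partial. Measured on 10 seeds at oracle per-point `(d, λ)` tuning, the mean
F1 is ≈ 0.65; it reaches ≈ 0.78 at 100 replicates/point and ≈ 0.87 at 200,
and per-point oracle F1 is 0.92–1.0 at 3000 (the estimator, not the sample
size, is then the only limit, and the residue is bump-edge ramp points
whose true weights are arbitrarily small). These numbers are recomputed by
`scripts/acceptance.py`.

### Staging positive control

`generate_regime_trajectory` plants `n_regimes` contiguous stages with
disjoint edge sets, at full strength on every grid point of their stage
(half-cosine ramps confined to the gaps between stages, so the profile is
continuous but the topology is stage-wise constant). The control for the
CNSI/clustering machinery uses p=15, three stages of three grid points,
seven edges per stage, and 200 replicates per grid point, estimated with
`h = 0.1` (below the grid spacing) and `d = 0`, λ = 0.2. The replicate
count is set so per-point support recovery is reliable
(`pcorr·sqrt(n) ≈ 4`): the property under test is the similarity analysis,
not estimator power, and any cross-boundary kernel or neighborhood
smoothing would blur the planted boundaries by construction — that blurring
is a documented consequence of the smoothness assumption, not a defect of
the staging analysis.

## Network analysis conventions

- Networks keep only connected genes; "nodes" means connected nodes.
- Density `2|E|/(|V|(|V|−1))`, 0 for fewer than two nodes. Diameter is the
  maximum shortest-path length over connected pairs (the largest component
  diameter); 0 for an edgeless network.
- CNSI: per node of `V(A) ∪ V(B)`, the Jaccard index of its first-neighbor
  sets (absent node → empty set, 0/0 → 0), summed and normalized by
  `|V(A) ∪ V(B)|`. The raw neighbor-overlap sum is unbounded; the
  normalization makes the score lie in [0,1] with 1 iff the networks are
  identical, consistent with similarity values reported as ≤ 1. Similarity
  of two empty networks is undefined and raises.
- Clustering: average linkage on `1 − CNSI` (robust for series of ~9
  networks); the flat cut into `n_stages` groups is reported alongside the
  dendrogram. For nine age groups the pipeline also reports the
  prior-knowledge three-stage partition (first three, middle three, last
  three groups) next to the data-driven cut.
- Hubs: the k highest-degree genes (default 3), ties broken
  lexicographically by gene id for determinism.

## Numerical choices and degenerate inputs

- Support tolerance 1e-6 on precision entries; ground-truth supports use
  1e-12 on generator weights.
- Variance ties in feature selection break by gene-id lexicographic order.
- Age encoding: prenatal ages are negative years, `−(40 − weeks)/52`; the
  child bin starts at 0.5 y so the nine verbal bins tile the axis; the last
  bin is closed at 120 y.
- Zero kernel mass at an evaluation time raises (advice: larger bandwidth),
  except inside CV where the nearest-sample fallback applies.
- `fit_series` with method "invar" requires a single shared λ and rejects
  per-point values.
- Config validation collects all structural errors before failing; pipeline
  failures name the failing stage.

## Limitations

- The nine-group-to-grid mapping is equally spaced; age-proportional
  coordinates are not implemented (the mapping is a single function if
  needed).
- Whether the reference analyses used exact or pseudo-likelihood mode is
  unknowable from their outputs; both are provided and cross-checked, with
  exact mode the default.
- Edge recovery at ~30 replicates per group is partial (see the power
  analysis); reported networks at that scale should be read through the
  cv.vote consensus, which trades recall for a low false-discovery rate.
- p is limited in practice by the ADMM eigendecompositions (O(|N|·p³) per
  iteration); a few hundred variables is the intended working range.
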