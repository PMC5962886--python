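# Methods

## Model

Each subject is represented by a T × R matrix of regional mean BOLD time
series (T timepoints, R regions; the package ingests already-extracted
regional series — voxel-level preprocessing, parcellation and band-pass
filtering are upstream). Optionally, each region's series is first replaced
by its OLS residual against an intercept plus nuisance regressors (CSF mean,
white-matter mean, motion parameters), and columns are z-scored (n−1
denominator) before any regression. The regressions are fitted without an
intercept; standardization is what makes the λ-fraction scaling comparable
across regions and subjects. Whether the original analyses standardized
before solving is not something the input data can tell us, so the package
fixes this convention and applies it uniformly.

For region m the sparse linear model `x_m = A_m α_m + τ_m` is solved under
three penalties (squared ℓ2 loss with the factor ½ throughout):

| method | objective | penalty scale |
|---|---|---|
| lasso | ½‖x−Aα‖² + λ‖α‖₁ | λ = fraction × λ_max, λ_max = max_j \|a_jᵀx\| |
| elastic net | ½‖x−Aα‖² + λ₁‖α‖₁ + λ₂‖α‖₂² | λ₁ fraction taken against the *lasso* λ_max; λ₂ fixed (default 0.2) |
| group lasso | ½‖x−Aα‖² + β Σᵢ‖α_{Gᵢ}‖₂ | β = fraction × max_i ‖A_{Gᵢ}ᵀx‖₂ |

Fractions live in (0, 1]; fraction 1 gives the empty model by construction
(exactly for lasso and group lasso, and for the elastic net by the λ₁
convention — a deliberate choice so the grid endpoint is interpretable even
with λ₂ > 0). Group norms are unweighted (no √|Gᵢ| factor); a size-weighted
variant is a one-line change in `solve_path` if wanted. The support of a
solution is {j : |α_j| > 1e-8}.

Lasso and elastic-net solves go through coordinate descent
(`sklearn.linear_model`), with the objective mapped onto sklearn's
(1/2n)-scaled parametrisation: `alpha = (λ₁ + 2λ₂)/T`,
`l1_ratio = λ₁/(λ₁ + 2λ₂)`. The group lasso is solved by FISTA with a block
soft-threshold proximal step, Lipschitz constant from the top eigenvalue of
AᵀA, and an explicit block-KKT stopping rule (residual ≤ 1e-6 × λ_max,
max 10 000 iterations, deterministic). Tests certify all three against exact
oracles: support-and-sign enumeration for lasso/elastic net (global optimum
by construction at R ≤ 8), and a Fenchel duality-gap certificate for the
group lasso.

## Hyper-network construction

For every centroid region m and every grid level, a hyper-edge is
{m} ∪ support(α_m). With the default 9-level grid a 90-region subject gives
exactly 810 hyper-edges (90 × 810 incidence matrix). Singleton edges (empty
support, e.g. at fraction 1) are retained and flagged rather than dropped,
and duplicate edges across levels are retained, so the incidence shape is an
invariant of (R, grid) — downstream code can rely on it. Multi-level
ascending prefix grids ({0.1}, {0.1, 0.2}, …) are available for the
elastic-net parameter sweep via `HyperNetworkSpec.prefix`.

The group-lasso branch needs a fixed partition {Gᵢ} of the regions. It is
learned once per cohort: pairwise similarity = Pearson correlation of the
time series averaged across training subjects (configurable to |r|),
dissimilarity = 1 − r, then k-medoids with the alternating
assignment/medoid-update scheme, seeded k-means++-style (first medoid
uniform, subsequent ones with probability proportional to the distance to
the nearest chosen medoid), 10 restarts, best cost kept, at most 100
iterations per run. The alternating update is used rather than swap-based
PAM because it is the form of the cited algorithm family and converges in a
handful of iterations at R = 90; the restart mechanism absorbs its greater
sensitivity to initialisation. Per-subject partitions are possible by
fitting the extractor on a single subject, but the cohort-pooled default is
what keeps Gᵢ identical across subjects, which the group penalty assumes.

## Features

Three hyper-graph clustering coefficients per node, with N(v) the
co-members of v's edges (v excluded) and S(v) the edges containing v:

* HCC¹(v) = 2 Σ_{u<t ∈ N(v)} I(u,t,¬v) / (|N(v)|(|N(v)|−1)) — pair (u,t)
  counts if some edge contains both but not v;
* HCC²(v) — same with I′(u,t,v): some edge contains u, t *and* v;
* HCC³(v) = (2 Σ_{e∈S(v)}(|e|−1) − |N(v)|) / (|N(v)|(|S(v)|−1)).

Pair sums run over unordered pairs with the leading factor 2 against the
ordered-pair denominator, so HCC¹ and HCC² lie in [0, 1]; HCC³ is
nonnegative but unbounded. N(v) excludes v itself — including it would put a
self-pair in every denominator and break the neighbourhood semantics.
Degenerate nodes (|N(v)| ≤ 1 for HCC¹/²; |S(v)| ≤ 1 or N(v) empty for HCC³)
score 0 and carry a flag; per-subject averages include the flagged zeros by
default (`drop_degenerate=True` excludes them). Totality matters: a
single-level grid leaves many nodes in one edge only, and a pipeline run
with such a grid emits an explicit degeneracy warning rather than NaNs.

## Statistics and classification

Per feature: two-sample KS statistic, p-value from uniformly drawn label
permutations with the +1 smoothing p = (1 + #{KS_perm ≥ KS_obs})/(1 + n_perm)
(default n_perm = 10 000 — resolution well below q/m for 270 features),
then Benjamini–Hochberg step-up at q = 0.05 over the feature family. The
permutation engine shares one permutation set across features of a table
(vectorised CDF differences with tie handling, cross-checked against
`scipy.stats.ks_2samp`). Relief weights (classic binary form, every instance
sampled once, Euclidean nearest hit/miss on standardized features) rank the
surviving features. Group-level average hyper-edges at a (centroid, λ) cell
take d = ⌈mean edge degree⌉ and the d most frequent members, ties broken
toward the lower region index.

Classification is an RBF-SVM. The outer loop is leave-one-subject-out; inside
every training fold, features are z-scored with training statistics only
(constant features map to 0) and (c, g) are chosen by exhaustive grid search
(default 2⁻⁸…2⁸, step 1 in the exponent) under stratified K-fold CV
(K = 10, reduced automatically when a class has fewer members), ties broken
toward smaller c then smaller g. Selecting (c, g) per outer fold keeps the
held-out subject out of every decision; a global-selection mode can be
emulated by calling `grid_search_cv` once and fixing single-point grids.
Patients are the positive class; BAC = (sensitivity + specificity)/2.
Feature *screening* is performed once on the full cohort before LOOCV; the
nested protections apply to standardization and hyper-parameter choice.

## Synthetic cohorts

The generator emulates a two-group resting-state cohort: default 28 controls
vs 38 patients, 90 regions, 238 retained volumes. Signal model per subject:

```
roi_j(t) = √ρ · B_block(j)(t) + √(1−ρ) · ε_j(t)
```

with every latent component stationary AR(1) (unit marginal variance;
default φ = 0.3, a moderate autocorrelation for TR ≈ 2 s series after
band-pass filtering), so the expected within-block correlation is exactly ρ
(default 0.4, six equal blocks — the scale of correlation seen between
functionally related regions). For patients, a shared AR(1) signal scaled by
the effect size (default 0.8) is added to the affected regions and to one
designated distant block, raising their mutual coupling; columns are
z-scored afterwards. Per-subject seeds derive deterministically from the
cohort seed (`SeedSequence.spawn`), so cohorts are reproducible at every
level.

What the generator does *not* emulate: hemodynamic response shape, scanner
drift and physiological noise spectra, motion artefacts, spatial
autocorrelation between neighbouring parcels, and between-subject
variability in connectivity structure (all subjects share the block layout).
Passing tests therefore demonstrate that the machinery recovers known
structure under clean conditions and stays calibrated under the null — not
that any particular clinical accuracy is attainable on real cohorts.

## Numerical and design choices

* Loss is ½‖·‖₂² (squared), the convention of the solver family the method
  descends from; closed forms and KKT conditions are standard under it.
* λ_min is treated as 0 in the fraction normalisation.
* Support tolerance 1e-8; solver KKT tolerance 1e-6 × λ_max (tightenable via
  `solve_path(..., tol=)`).
* k-medoids cost is the sum of dissimilarities to assigned medoids; a medoid
  always belongs to its own group, so all k groups are non-empty.
* Hyper-edges are sets; member order never carries meaning. Nodes are
  0-based internally, 1-based labels in all serialized output.
* Orthogonal-response degenerate case (λ_max = 0): every penalty level
  returns the empty model rather than erroring.
* Test and acceptance problem sizes (6–20 regions, 28–40 subjects, 60–150
  timepoints, reduced c/g grids) are chosen so the full statistical suites —
  200 null replicates, nested LOOCV — run comfortably on one CPU while
  keeping the group-size ratio and feature-to-subject ratios of the
  emulated cohort design.

## Limitations

* The group-lasso branch inherits k-medoids seeding stochasticity; results
  are reported as mean ± sd over repeated seeds (`sweep_k`, default 50
  repeats) rather than as a single number.
* FDR family boundaries follow one correction per feature table; analyses
  that pool several tables should correct jointly.
* The Relief implementation is the classic binary form (no k-nearest
  averaging, no missing-value handling).
* Weighted hyper-edges are out of scope: coefficient magnitudes are
  discarded after support extraction by design.
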