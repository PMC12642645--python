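# Methods

## The model

The package treats a functional-connectivity matrix as a complete
weighted graph on n ROIs: `A` is symmetric, real-valued (temporal
correlations, typically in [−1, 1]) with a unit diagonal that carries no
information and is excluded everywhere. The weighted stochastic block
model (WSBM) assumes each ROI has a latent community label
`z_i ∈ {1..K}` with a flat prior `P(z_i = k) = 1/K`, and that
conditional on the labels the off-diagonal weights are independent
Gaussians whose mean and variance depend only on the unordered
community pair:

    A_ij | z ~ N(mu[z_i, z_j], sigma2[z_i, z_j]),   i < j.

Nothing here prefers assortative structure: within-community means may
be smaller than between-community ones, so disassortative and
core–periphery patterns are representable. The conjugate prior on each
block pair is normal–inverse-gamma (NIG):
`mu | sigma2 ~ N(m0, sigma2/kappa0)`, `sigma2 ~ InvGamma(a0, b0)` —
the conjugate exponential family for the natural parameters
`(mu/sigma2, −1/sigma2, −mu²/sigma2)`.

### Variational inference

The posterior over `(z, mu, Sigma)` is approximated by a mean-field
factorization `q(z) q(eta) = ∏_i q(z_i) ∏_{a≤b} q(mu_ab, sigma2_ab)`,
chosen to minimize the KL divergence to the true posterior. Updates are
exact coordinate ascent on the ELBO:

* **Block update.** Given responsibilities `R`, each `q(mu_ab,
  sigma2_ab)` is NIG with sufficient statistics accumulated over
  responsibility-weighted unordered pairs (expected count, weight sum,
  squared-weight sum).
* **Responsibility sweep.** Nodes are updated one at a time (a
  synchronous update would not be a coordinate step and can decrease
  the objective). The expected log densities are linear in `(1, A_ij,
  A_ij²)`, so the sweep maintains `A@R` and `A²@R` incrementally and
  costs O(n²K); it is compiled with numba.

Because both steps are exact, the ELBO trace is non-decreasing up to
floating point (asserted at tolerance 1e-6 in the tests). Convergence is
declared when the relative ELBO change drops below `tol = 1e-6`, with a
cap of `max_iter = 200`.

### Initialization and restarts

Symmetric random initializations (e.g. i.i.d. Dirichlet responsibilities
per node) put all block posteriors at essentially the same fat Gaussian,
a saddle from which coordinate ascent collapses every node onto one
label. Each restart therefore seeds the responsibilities from a
kmeans++-style pass over connectivity profiles: K anchor ROIs chosen by
farthest-point sampling on the `1 − corr` profile distance, a short
Lloyd refinement, and sharp (0.99) responsibilities. Anchor choice is
random per seed, which is what gives restart ensembles their diversity.

Ensemble members (`fit_ensemble`) additionally run a small number of
internal trials (`n_trials = 5`, the scheme reference WSBM codes use)
and keep the best, preferring solutions that use all K labels and then
the higher ELBO. A solution whose MAP labels use fewer than K distinct
communities is *invalid* and is discarded from the pool (counted in
`n_invalid`).

### Two per-fit scores

* `loglik` — the plug-in log-likelihood: the Gaussian likelihood at MAP
  labels and posterior-mean parameters. Used to pick the single best
  solution at a fixed K ("highest log-likelihood" rule).
* `elbo` — the final variational objective, VB's approximation of the
  marginal likelihood log P(A | M). Used by default for model selection
  across K, because the selection statistic is a Bayes factor and
  because the plug-in likelihood increases monotonically with K (a
  valid K+1 solution always fits noise strictly better), which would
  make a difference-based stopping rule undecidable. Selection with the
  plug-in statistic remains available (`statistic="loglik"`).

## Choosing K

For each K in the grid (consecutive integers, default 2..20; the
synthetic benchmark uses 2..8) a pool of criterion values is collected
from valid ensemble solutions. For each transition K → K+1 a percentile
bootstrap CI of the difference is formed: each replicate draws one value
with replacement from each pool and records the difference (`mode=
"pairs"`; a difference-of-resampled-means mode exists behind a flag).
Defaults: 95% intervals, 2000 replicates (500 in the benchmark).

**Stopping rule.** K* is the smallest K whose interval is *not strictly
positive* — it contains 0 or lies entirely below it. An entirely
negative interval means K+1 made the criterion worse, which is stronger
evidence to stop than straddling 0; treating only exact straddles as
stops would overshoot. Two boundary cases:

* If no valid (K+1)-community solutions exist at all, the data cannot
  support K+1 communities and the search stops at K.
* If every evaluable transition is strictly positive, the grid maximum
  is returned with `no_overlap_fallback = True` rather than failing
  silently.

The reported final solution at K* is the valid fit with the highest
plug-in log-likelihood (ties broken by smaller seed).

## Baseline clusterers

* **Correlation K-means** works on the rows of `A`. The dissimilarity
  between a row and a centroid is `1 − Pearson`. Centroids are
  arithmetic means of member rows — a surrogate, since no closed-form
  minimizer exists under the correlation metric — so the objective is
  re-checked each iteration and the loop stops (keeping the previous
  assignment) if it would rise; the recorded trace is non-increasing.
  Convergence is otherwise on stable assignments, cap 300 iterations.
  Empty clusters are re-seeded at the worst-fitting ROI (never stealing
  a singleton), keeping K fixed. Best of `n_restarts` by within-cluster
  dissimilarity.
* **Spectral clustering** builds profile dissimilarities `d_ij = 1 −
  r_ij`, similarities `S_ij = exp(−d_ij²)`, and the unnormalized
  Laplacian `L = D − S` where the degree excludes the self-similarity
  (equivalently, S's diagonal is zeroed; each row of L then sums to 0
  and L is PSD). ROIs are embedded as rows of the eigenvector matrix of
  the K smallest-magnitude eigenvalues — implemented literally as a
  sort on |λ|, though L being PSD makes this the plain smallest K — and
  clustered by seeded Euclidean K-means. Embedding rows are not
  length-normalized (unnormalized algorithm).

For both baselines the final solution at a given K is the replicate
with the highest silhouette.

**Profile correlations and the diagonal.** When correlating rows i and
j of a symmetric unit-diagonal matrix, coordinates i and j carry the
forced values `A_ii = A_jj = 1` and would bias the correlation; they
are excluded by default (closed-form corrected sums keep this O(n²)).
A toggle restores plain row correlations.

## Indices

All logarithms are natural. Dissimilarity-based indices (silhouette,
CH, C-index, Dunn) take the profile dissimilarity matrix.

* Silhouette: mean of `(b_i − a_i)/max(a_i, b_i)`; ROIs in singleton
  communities score 0 (common convention); undefined for K = 1.
* Modularity: `Q = (1/2m) Σ_ij (A_ij − d_i d_j / 2m) 1{z_i = z_j}` over
  ordered pairs. The unit diagonal is zeroed before computing degrees
  and m (toggleable); negative weights enter as-is.
* CH index: pseudo-F on squared dissimilarities with
  `SST = (1/n) Σ_{i<j} d²_ij`; note this normalization can make the
  among-group sum negative for poor partitions, so CH may be negative.
  SSW = 0 returns +inf.
* C-index: `(SW − Smin)/(Smax − Smin)` with Smin/Smax the sums of the
  NW smallest/largest of all pairwise dissimilarities.
* Dunn: minimum single-linkage between-community distance over maximum
  community diameter.
* VI distance: `H(C1) + H(C2) − 2 I(C1, C2)` — the form with the factor
  2, which is required for VI(C, C) = 0.
* NMI: geometric-mean normalization `I/√(H1 H2)` (arithmetic-mean
  normalizations exist in the literature; the geometric form is what
  scikit-learn's `average_method="geometric"` computes, which the tests
  cross-check). Two single-community partitions get NMI 1; exactly one,
  0.
* Hamming: minimum mismatch fraction over all label permutations,
  solved exactly with the Hungarian algorithm on the label-agreement
  matrix; the tests verify it against exhaustive K! search.

## Consensus

Given solutions at a fixed K, a reference is chosen (first solution,
explicit index, or the maximum of caller-supplied scores — plug-in
log-likelihoods for WSBM pools, silhouettes for baselines), every other
solution is relabeled by its Hamming-minimizing permutation, and each
ROI takes its modal label across the aligned solutions (ties to the
smaller label, deterministically). The consensus of pure relabelings of
one partition reproduces it exactly; if the consensus uses fewer than K
labels it is returned with `uses_all_labels = False` rather than
rejected.

## Synthetic generator

The generator emulates a resting-state cohort's group-level FC matrix:
n = 100 ROIs in K = 5 planted communities of sizes 30/15/25/20/10.
Per network, block means are drawn uniformly — within-community from
[0.3, 0.6], between-community from [−0.05, 0.2] — and block standard
deviations from [0.05, 0.15]; each edge weight is then one Gaussian
draw. These ranges are meant to bracket the within-/between-system
correlation levels seen in adult resting-state data while leaving the
exact block layout random; all are overridable. Draws are clipped to
[−1, 1] by default so entries remain interpretable as correlations
(with the default ranges clipping is almost never active); `clip=False`
gives the pure Gaussian model. ROIs are laid out contiguously by
community — every method in the package is permutation-equivariant — 
with an optional seeded shuffle.

What the generator does *not* emulate: the sampling noise structure of
estimated correlation matrices (edges sharing an ROI are correlated in
real data; here they are independent), positive-semidefiniteness,
subject-level variability, spatial autocorrelation, and any
non-Gaussian tail behavior. Passing the synthetic benchmark therefore
shows the machinery is correct and the selection rule calibrated under
the model's own assumptions — not that K selection is unbiased on real
cohorts.

## Numerical choices and determinism

* NIG prior defaults: `m0 = 0, kappa0 = 1, a0 = 2, b0 = 0.1` (prior
  variance mean 0.1) — weakly informative on the correlation scale.
* Posterior-mean variance reported as `b/(a−1)` (a > 1 always holds
  with `a0 = 2`).
* MAP-label ties break toward the smaller label index; so do
  majority-vote ties in the consensus.
* Every stochastic stage takes an explicit seed; nested seeds are
  derived with `numpy.random.SeedSequence`, and reports record them.
  Identical seeds give byte-identical outputs.
* The benchmark budgets (100 restarts per K, 500 bootstrap replicates,
  K = 2..8, 10 master seeds) were chosen so a full benchmark pass runs
  in minutes on one CPU; the full-scale budgets (1000 restarts, 2000
  replicates, K up to 20) are supported through the same interfaces.

## Known limitations

* The VB fit is a local optimizer; recovery claims hold for the
  restart-ensemble protocol, not for a single run.
* Valid solutions with K above the true community count become rare
  (the Occam penalty of the marginal criterion actively empties extra
  blocks), which is precisely what the empty-pool stopping case
  handles; on data with weak or hierarchical structure the selected K
  can sit below the visually apparent number of modules.
* The C-index and CH index follow their literal definitions above;
  other software may use unsquared distances (CH) or different SST
  normalizations, so absolute values are not comparable across
  packages.
* `modularity` with signed weights follows the plain formula; dedicated
  signed-modularity variants are out of scope.
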