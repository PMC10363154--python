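# Methods notes

## Model and assumptions

The engine treats differential activity as a density-comparison problem.
The sample distribution over the input space is summarized at `g` grid
points by a Gaussian kernel: `Q_j ∝ Σ_i exp(-(‖s_i − grid_j‖/h)²/2)`. A
feature's activity-weighted analogue `P_f` re-weights the same kernel
contributions by `y_{f,i}`, so `P_f = Q` exactly when activity is constant,
and `D_KL(P_f‖Q)` (natural log; `0·log 0 := 0`) grows with any positional
bias of activity. Assumptions worth keeping in mind:

- Activity must be non-negative — values act as weights. Signed inputs
  (module scores, scaled data) must be min-max rescaled per feature first
  (`rescale_activity`).
- `Q_j > 0` always holds because the Gaussian kernel is strictly positive,
  so the divergence never divides by zero; `P_{f,j} = 0` is allowed (sparse
  features) and contributes nothing.
- The null calibration assumes that permuting a feature across samples is
  the right null (no sample-level covariates), and that the null
  distribution of `log D_KL,random` depends on the feature only through its
  coefficient of variation. Both mirror how the statistic is constructed:
  D_KL after permutation depends on the activity vector only through its
  (exchangeable) empirical distribution, and CV is its dominant summary.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `g` | 100 | grid points; k-means centroids cover the occupied subspace roughly uniformly. Lower for few samples, higher for very heterogeneous data. |
| `h` | median nearest-grid distance | kernel bandwidth; adapts to grid density, unitless after coordinate standardization. |
| `m_reference` | 100 | features used to learn the null moments, spread evenly over the **log** CV range (the modeling scale; linear spacing is available as `scale="linear"`). Min- and max-CV features are always included so prediction never extrapolates. |
| `n_permutations` | 100 | replicates per reference feature; enough for stable mean/sd of a log-normal-ish sample. |
| spline df | CV-selected | natural cubic splines, df 1–10 (B-splines: degree 1–5 × df 1–10), tenfold CV on mean squared prediction error, folds from a seeded shuffle, ties toward the least flexible candidate. Mean and sd curves are selected independently; the sd curve is fitted on the natural scale and floored at 1e-6. |
| `seed` | 42 | drives k-means, permutations and fold assignment; identical seeds give byte-identical outputs. |

Coordinate scaling uses the sample standard deviation (n−1). Zero-variance
columns are centered and kept as zeros so column indices stay stable.
`g > n` is clamped to `n` (permissive for tiny inputs). The test is
one-sided: only divergence above the null mean is significant; depleted
divergence is never reported.

P-values are computed and reported on the log10 scale throughout
(`norm.logsf` then divided by ln 10), so extreme significances (z = 40 →
log10 p ≈ −348) never underflow. Benjamini–Hochberg adjustment is applied
on the same scale and is secondary output; unadjusted log10 p is the
primary ranking key, with ties broken by larger divergence, then input
order. Features with zero total activity are flagged `all_zero` and kept
in the output (NaN statistics) so row alignment with the input is
preserved; zero-CV / zero-divergence features are flagged `zero_cv` with
p = 1. Out-of-span log CV values are clamped to the reference span rather
than extrapolated — spline behavior outside training support is untrusted.

## Spline implementation

The natural cubic basis is built in-package with the truncated-power
construction (boundary knots at the data extremes, interior knots at
quantiles; df = 1 is exactly a straight line; linear beyond the boundary),
B-spline design matrices come from scipy. Fits use least squares
(`lstsq`, minimum-norm under rank deficiency), which keeps selection fully
deterministic.

## Synthetic data: what it emulates and what it does not

`make_coords` produces three archetypes: Gaussian blobs (clustered latent
embeddings; centers ≥ 3 units apart in [−5,5]^d with blob sd 0.5, so
cluster recovery is unambiguous), a uniform unit hypercube (tissue-like
spatial layouts) and sorted U(0,1) pseudotime. `make_activity` plants a
Gaussian bump of rate `baseline + amplitude·exp(−‖s−c‖²/2w²)` at a center
drawn from the sample coordinates, with Poisson (UMI-like, default) or
lognormal noise; defaults baseline 0.5, amplitude 2 ("moderate"; 8 is used
as the strong regime), width 1 — about one blob radius, so a planted
effect covers a biologically plausible sub-population. Null features use
the same rate recipe permuted across samples: identical marginal
distribution, exchangeable by construction, which is exactly the null the
permutation test assumes. Trajectory patterns use width 0.08 and amplitude
4 on the [0,1] pseudotime axis — a bump must be narrow relative to a 1D
domain to be local at all.

Not emulated: dropout beyond Poisson sparsity, batch effects, doublets,
gene–gene correlation, or the continuum of weak spatial structure that
real tissue data carries in almost every gene. Consequently, calibration
results here show the engine is correct under its own null; they do not
certify error rates on real data, where no gene is perfectly exchangeable.

## Numerical and design choices

- Natural log for D_KL; the base cancels in p-values since the null uses
  the same base.
- Vectorized D_KL is one sparse matrix product (`activity @ density`) plus
  row normalization; tested to 1e-12 against a per-feature loop and across
  sparse/dense storage.
- Permutation replicates are generated in blocks of 500 so the permuted
  matrix never exceeds a few hundred MB at typical n.
- Reference features whose permutation replicates are all zero (constant
  features) are dropped with a warning; fewer than 12 usable references is
  an error (ten folds need headroom).
- Gene-set scores are the mean of member features' max-normalized
  activity, min-max rescaled to [0,1] per set. This is *not* Seurat's
  AddModuleScore (no expression-bin-matched control subtraction); it is a
  deliberately simple score whose purpose is to produce set-level
  activities the engine can test.
- Module clustering uses `P_f` profiles: k-means on per-feature
  standardized profiles (seeded, n_init=10), or hierarchical clustering
  with correlation distance (1 − Pearson) and average linkage, returning
  the dendrogram leaf order plus a k-cut.

## Problem sizes

The test suite and acceptance script run on 1,000-sample / 2,000-feature
studies for calibration and recovery, 10,000 direct permutations for the
agreement check, and 600 samples × 1,000 features for the trajectory
study — sizes at which every quantity of interest is stable across seeds.

## Known limitations

- Rankings of *null* features are not reproducible across grid sizes: a
  null feature's D_KL is a functional of its random position–activity
  association evaluated at kernel scale `h`, and grids with different `h`
  measure different projections of that noise (Spearman of null log10 p
  between g = 50 and g = 200 is ≈ 0.5 on fully exchangeable synthetic
  nulls). Top-ranked features with real structure are stable; the long
  uniform tail is not, and should never be interpreted.
- A single k-means run decides the grid; a different seed gives a slightly
  different grid and slightly different p-values (identical seeds are
  fully reproducible).
- No two-condition contrast: the method flags non-random activity in one
  dataset, not differences between datasets.
- CV-based null prediction can misestimate for features whose activity
  distribution is unusual for their CV (e.g. heavy ties at one value);
  the permutation-agreement check bounds this at about a tenth of an
  order of magnitude under the synthetic conditions above.
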