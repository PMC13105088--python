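# Methods

This note documents the statistical machinery implemented in `cortmatch`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## The correspondence problem

All analyses operate on vectors with one value per parcel of a shared
cortical parcellation (the bilateral 180-area resolution of common
multimodal atlases is the reference scale). The scientific question —
whether a target map spatially resembles a panel of cortical feature maps
— is a question about *spatial* association, and both map types are
strongly spatially autocorrelated: nearby parcels carry similar values.
Classical permutation tests assume exchangeability of parcels and
therefore overstate significance, sometimes severely (the calibration
study in `analysis/02` measures a several-fold inflation). Every
inferential statement in this package is instead referred to a null of
*variogram-matched surrogate maps*.

## Variogram estimation

The smoothed empirical semivariogram of a map x on geometry distances
d_ij is

    gamma(h_k) = sum_{i<j} w_k(d_ij) (x_i - x_j)^2 / 2  /  sum w_k(d_ij),
    w_k(d) = exp(-(d - h_k)^2 / (2 b^2)),

evaluated at `nh` uniformly spaced lags h_k between the smallest positive
pairwise distance and the `pv`-th percentile of pairwise distances, with
Gaussian kernel bandwidth b = `bandwidth_factor` × lag spacing.

Parameters, defaults and rationale:

* `nh = 25` lags by default. The full-analysis pipeline raises it to 50;
  finer lag grids let the surrogate matching track the target's variogram
  more closely at the cost of noisier per-lag estimates.
* `pv = 25`: distant parcel pairs are sparse on a bounded domain and
  their semivariance estimates are noisy; truncating at the 25th distance
  percentile concentrates the fit where the data are dense and where
  autocorrelation actually lives.
* `bandwidth_factor = 3`: deliberate oversmoothing stabilises the curves
  used for surrogate matching. Two estimator properties follow and are
  worth knowing: heavily smoothed estimates are biased wherever the true
  variogram is curved, and the first lag — at the edge of the
  pair-distance support, where the kernel can only average one-sidedly —
  is biased upward. The oracle tests that compare against the closed-form
  exponential variogram therefore use `bandwidth_factor = 0.5` and skip
  the edge lag; the brute-force equivalence test runs at the default.
* Lags start at the minimum positive distance, not zero, so the
  degenerate self-pair bin never enters.
* A constant map has gamma ≡ 0; this is valid output, not an error.

Quantile bands over variogram ensembles use linear interpolation between
order statistics (numpy's default quantile definition).

## Surrogate generation

Each surrogate of a target x is built as:

1. permute x uniformly at random across parcels;
2. for each neighbourhood fraction delta in {0.1, ..., 0.9}: smooth the
   permutation by a kernel-weighted average over each parcel's
   k = max(1, round(delta·P)) nearest neighbours (self excluded; the
   kernel scale is the distance to the k-th neighbour). The default
   kernel is exponential, with gaussian / uniform / inverse-distance
   available;
3. regress the target's variogram on each candidate's
   (gamma_t ≈ alpha·gamma_c + beta over the nh lags) and keep the delta
   with the smallest SSE;
4. return sqrt(|alpha|)·smoothed + sqrt(|beta|)·epsilon, with epsilon an
   i.i.d. normal vector standardised to mean 0, variance 1 (population
   normalisation) per surrogate.

The linear identity gamma(a·x + independent noise) = a²·gamma(x) +
var(noise) is what makes the rescaled candidate's variogram approximate
the target's. Absolute values under the square roots guard against the
slightly negative intercepts that least squares can produce on
short-range maps; standardising epsilon first makes sqrt(|beta|) directly
interpretable as the added nugget amplitude.

`resample_values` optionally maps each surrogate's ranks onto the sorted
target values, forcing the target's exact value distribution. It defaults
to off: every downstream statistic here is rank-based, so value-marginal
matching changes nothing inferentially and discards the amplitude
information in alpha/beta. Turn it on for display-faithful surrogates.

Reproducibility: a single seed spawns one independent child RNG stream
per surrogate, so surrogate i is a pure function of (seed, i) regardless
of batch size. (Batched and single-surrogate evaluation may differ in the
last floating-point ulp because BLAS reassociates sums across batch
shapes; statistically they are the same stream.)

The neighbourhood smoothing matrices and variogram kernel weights depend
only on the geometry and are precomputed once per generator; ensembles
are evaluated in batches of 512 surrogates as dense matrix products.

## The screen

Observed Spearman rho per feature is referred to the null distribution of
correlations between that feature and the target's surrogates — one
shared ensemble generated from the target only, never from the features.
The two-sided p-value is the doubled add-one tail,

    p = min(1, 2·min(1 + #{null ≤ rho}, 1 + #{null ≥ rho}) / (S + 1)),

chosen because it is a valid p-value (never zero, self-inclusive) and
symmetric; a |rho|-tail variant would differ negligibly for the
near-symmetric nulls seen here. The three multiplicity rules each act on
the same unmodified p-values: Bonferroni compares p to alpha/F,
Benjamini–Hochberg is the classical step-up (via statsmodels), and the
uncorrected rule compares to its own alpha. Ties anywhere receive average
ranks.

## Rank regression

The target and each predictor are independently rank-transformed
(average ranks, 1 = lowest) before an OLS fit with intercept; R² is the
standard centred coefficient of determination, and with a single
predictor it equals the squared Spearman correlation exactly. The
surrogate test re-ranks every surrogate, refits it on the same predictor
ranks (vectorised through one thin-QR projection), and reports

    p = (1 + #{R²_surrogate ≥ R²_observed}) / (S + 1)

one-sided, along with the null R² median. The key behaviour — verified in
the acceptance suite — is the *smoothness asymmetry*: predictors whose
spatial covariance matches the target's achieve systematically higher R²
on the surrogates too, raising the null median and weakening the
evidence carried by a given observed R²; rough predictors do not.

Designs with condition number above 1e8 (after adding the intercept) are
rejected with the offending predictor pair named, rather than silently
pseudo-inverted. Residuals are observed rank minus fitted rank; positive
values mark parcels where the target is higher than the model predicts.

## Mismatch maps

Both maps are rank-transformed; if their Spearman correlation is strictly
negative the feature's ranks are reversed (rank → P + 1 − rank) so every
comparison points the same way; a correlation of exactly zero does not
trigger reversal (configurable in principle; reversal of an uncorrelated
map is arbitrary either way). Δr_i = rank(target)_i − rank(feature)_i
sums to zero by construction, with or without ties. Group aggregation
reports mean |Δr| sorted descending, with ties in the mean ordered by
group label. Majority-vote network assignment counts group labels over
each parcel's voxels after nearest-neighbour resampling onto the parcel
grid, excludes background, breaks ties toward the lowest group label
(recorded in a tie report), and refuses parcels with no overlap — callers
must supply an explicit fallback table rather than getting silent drops.
No per-parcel inferential statistic is attached to Δr; the maps are
descriptive.

## Geometry and parcellation

Parcel distances default to Euclidean distances between volumetric parcel
centroids (computable from any label atlas alone); any precomputed P×P
matrix — e.g. surface geodesic distances — can be supplied instead and is
used verbatim. Voxel-to-parcel aggregation assigns each labelled voxel
the value of its nearest stat point (voxel-centre mm coordinates through
the affine; exact ties go to the lowest point index for determinism) and
averages within parcels. Bilateral merging is the voxel-count-weighted
mean of the two hemisphere means, which is identical to averaging over
the pooled bilateral mask; an unweighted variant is available. Parcel
tables are matched by explicit `parcel_id` — positional alignment across
files is never assumed.

## Synthetic test bed

The generator produces Gaussian random fields with exponential covariance
C(d) = sill·exp(−d/range) + nugget·1{d=0} on P quasi-uniform sphere
points (golden-ratio spiral). Defaults — P = 180, radius 80 mm,
range 30 mm, sill 1 — are on the scale of a bilateral cortical
parcellation, so surrogate defaults behave as they would on real parcel
geometries. The exponential family was chosen because its variogram has
the closed form sill·(1 − e^(−h/range)), giving the estimator an exact
oracle.

Scenario builders: coupled pairs mix a target draw with an independent
draw (feature = w·target + (1−w)·independent; w = 0.8 produces realized
Spearman ≈ 0.9–0.97 at P = 180), and regression scenarios form
y = Σ rank(x_j) + noise_scale·rank(GRF noise) over three independent GRF
predictors. `noise_scale = 2.59` was calibrated once by a 10,000-replicate
pilot (seed 20260901) to put the mean realized rank-R² at 0.3009
(sd 0.0822); the values are frozen in
`cortmatch.synthetic.REGRESSION_CALIBRATION` and never re-tuned. Note one
structural subtlety: with several predictors and zero noise the fit is
near-perfect but not exact (R² ≈ 0.93–0.99), because the rank transform
of a summed-rank response is monotone in, but not linear in, the
individual predictor ranks; the single-predictor case is exact.

What the synthetic bed does *not* emulate: real cortical geometry
(surface folding, interhemispheric structure), nonstationary smoothness,
heavy-tailed or discretised value distributions of expression maps, and
measurement artefacts. Passing tests therefore establish the statistical
machinery — calibration, power, matching, exactness of the algebra — not
the biological conclusions one would draw on any particular dataset.

## Known limitations and honest numbers

* The replicate spread of the rank-R² estimate at P = 180 with 30 mm
  predictors is large: sd ≈ 0.082 in the pilot, so individual replicates
  commonly land 0.1 or more from the population value (only about two
  thirds fall within ±0.08). This is a property of the effective spatial
  sample size, not of the fitting code; the acceptance suite states the
  stricter recovery bound it checks and reports honestly against it.
* Two-sided surrogate p-values are granular in 2/(S+1) steps; S must be
  chosen with the smallest p of interest in mind (the pipeline default of
  100,000 surrogates resolves p ≈ 0.0005 comfortably; the shipped demo
  config uses S = 200 for speed).
* The surrogate test is mildly conservative at study scale. Across
  ~1,750 simulated independent map pairs (P = 180, 30 mm fields) the
  two-sided rejection rate at alpha = 0.05 measures near 0.025–0.03
  rather than 0.05: the per-surrogate neighbourhood selection sometimes
  picks a strongly oversmoothed candidate whose rescaled form matches the
  variogram but carries heavier-tailed correlations with any fixed smooth
  map, overdispersing the null by ~10–15% in sd. The effect is a property
  of the published algorithm (it persists under either self-inclusion
  convention, either p-value convention, and at nh = 25 or 50); it errs
  on the safe side, and is an order of magnitude smaller than the
  anticonservatism of the naive permutation null it replaces (~0.22 at
  the same nominal 0.05). The surrogate model also only controls the
  global autocorrelation profile; locally inhomogeneous smoothness is not
  matched.
* Simulation sizes in tests and `scripts/acceptance.py` (hundreds of
  pairs/replicates, S = 300–1000) were set so the full suite runs on one
  CPU in minutes while keeping Monte-Carlo error a few percentage points;
  all are ordinary function arguments and scale up freely.
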