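# Methods

This note documents the models and algorithms implemented in `nichemargin`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Reduced climatic space

The environmental space is a PCA calibrated on **all valid pixels** of the
climate grid, not on any species' range, so that every species' niche and
every site is placed in one common plane. Because the input variables mix
units (°C, mm, dimensionless indices), the PCA operates on centered,
**unit-variance** variables (correlation PCA); without scaling,
high-variance precipitation variables would dominate the axes. Scaling can
be disabled (`scale=False`) for pre-standardized inputs. Standardization
uses the sample standard deviation (ddof = 1).

Two axes are retained by default — niche envelopes are inherently 2-D
objects here — and the retained count is configurable upward for distance
work. Axis signs are fixed deterministically (the largest-magnitude loading
of each axis is made positive) so that envelopes and scores are
reproducible across runs and platforms. Eigenvalues of the correlation
matrix sum to the number of variables, which the tests use as a
conservation invariant.

Coarser-resolution sensitivity analyses use block-mean aggregation.
Partial edge blocks (grid not divisible by the factor) are averaged over
the fine cells available; a coarse cell is masked only if every contributor
is masked.

## Niche envelopes

**KDE highest-density region.** The realized-niche envelope is the region
{density ≥ t} of a bivariate Gaussian KDE of the range-pixel scores, with t
chosen so the region holds the stated fraction (level) of the estimated
density mass. "Contour at level p" is therefore a *mass* statement (the
highest-density region), not a fraction-of-peak-density statement; this is
the documented semantics of the kernel contouring convention this field
uses. Numerically:

- bandwidth: the normal-reference full-covariance matrix (for d = 2 this
  equals Silverman's factor applied to the data covariance, `n^{-1/3} Σ`),
  with Scott's factor as the alternative. A multistage plug-in bandwidth
  would be marginally less smooth; the normal-reference matrix is a
  well-understood, dependency-free default and its oversmoothing is within
  the tolerances the tests assert (e.g. 95% HDR area within ±10% of the
  analytic value for 5,000 Gaussian points).
- density evaluated on a 500×500 grid spanning the data range expanded by
  10% per side; the threshold is found by sorting grid mass (no iterative
  root finding); contours extracted by marching squares on a zero-padded
  grid so every ring closes.
- rings are assembled into polygons-with-holes by even-odd containment
  depth; rings with area below 1e-6 of the total are discarded as
  contouring noise.
- the enclosed mass is re-integrated over the returned polygons and must
  match the level within ±0.01, or construction fails loudly (an
  out-of-range threshold usually means the evaluation grid was too small).

Degenerate inputs (all points identical, or rank-deficient covariance)
raise an error suggesting jitter rather than returning a zero-area
envelope.

**Minimum-volume ellipsoid.** The fundamental-niche proxy peels the
farthest point by Mahalanobis distance (mean and covariance recomputed
after each removal) until ⌈level·n⌉ points remain, then fits the exact
minimum-volume enclosing ellipsoid of the retained set by Khachiyan's
algorithm (relative tolerance 1e-6). Two post-steps guarantee the
documented contracts: the shape matrix is rescaled so every retained point
is inside boundary-inclusively (the iteration's finite tolerance otherwise
leaves support points ~1e-5 outside), and the 256-gon polygon
representation circumscribes the ellipse (vertices scaled by 1/cos(π/256))
so the polygon never excludes ellipse-interior points. Collinear inputs
raise (degenerate ellipsoid).

## Niche Margin Index

The signed margin distance is the minimum Euclidean distance to **any**
boundary ring (outer rings and holes), positive iff the point lies in the
union of outer rings minus holes; a point inside a hole is outside the
niche. Distances are computed in the retained 2-D plane; a k-D signed
distance to ellipsoidal envelopes is provided
(`ellipsoid_signed_distance`, by root-finding on the Lagrange multiplier of
the closest-point condition) for workflows that keep more axes.

The standardization denominator is the maximum, over a regular interior
lattice of ~10,000 points, of the minimum distance to the margin — the
depth of the niche's deepest point (a Chebyshev-center approximation).
Choices:

- the lattice is a square grid with spacing s = √(area/n), origin fixed at
  the bounding-box lower-left + s/2, so results are bit-reproducible; the
  spacing is halved (up to 30 times) if a degenerate sliver admits no
  lattice point.
- for multi-polygon envelopes a **single** denominator is taken across all
  fragments: one species gets one scale, preserving comparability of its
  sites. (Whether disjoint fragments should each carry their own
  denominator is genuinely open; the shared denominator is this package's
  documented choice.)
- the denominator is cached on the envelope per lattice size.

Consequences of the lattice: the denominator underestimates the true depth
by O(s), so NMI can exceed 1 by about one lattice spacing near the exact
deepest point, and similarity invariance of NMI holds to lattice tolerance
(~1–2%) while the unstandardized distances are exact. The tests assert
exactly these tolerances.

## Establishment model

Establishment success of release event i of species s is Bernoulli with

    logit(ψ) = α + α_species(fam) + α_family + α_region + β·NMI + Σ_c β_c·x_c

Ten fixed-effect columns: NMI plus nine covariates. Propagule size, weaning
age, native range area, introduction date and litter size are
natural-log-transformed before z-scoring (date included, literally, despite
its near-linearity over the observed span — flagged here because ln(year)
is nearly affine and the standardized column is almost identical to the
unlogged one). The island flag stays binary with mainland as reference, so
α is the average mainland success on the logit scale; z-scoring an
indicator would destroy that interpretation. z-scores use the sample sd
(ddof = 1) over observed entries only.

Priors: fixed effects Normal(0, precision 0.1) (sd ≈ 3.16); random-effect
sds half-Cauchy with scale 5 (a weakly-informative default; the scale is
configurable); imputation means ν_c ~ Normal(0, 10), imputation sds
half-Cauchy(5). Missing covariate cells are assumed MCAR, modeled
x_c ~ Normal(ν_c, σ_c), and sampled jointly with all other unknowns, so
imputation uncertainty propagates into every posterior; columns with no
missingness bypass the imputation layer.

**Sampler.** Pólya-Gamma data augmentation makes every full conditional
tractable: ω_i ~ PG(1, η_i) turns the Bernoulli likelihood Gaussian in the
linear predictor, giving closed-form Gibbs updates for the fixed-effect
block (joint multivariate normal), each random-intercept vector, each
missing cell and each ν_c; the half-Cauchy scales use the standard
inverse-gamma parameter expansion. Two refinements matter in practice:

- PG(1, z) variates are drawn from the truncated infinite-series
  representation (64 terms) plus the analytic mean of the discarded tail,
  preserving the first moment to O(K⁻²); the neglected tail variance is
  O(K⁻³) and immaterial (verified against E[PG(1,z)] = tanh(z/2)/(2z)).
- each variance component gets an interleaved **ancillary rescaling step**
  (ASIS): writing a = σ·ã, the PG likelihood is exactly Gaussian in σ, so a
  proposal from that conditional is Metropolis-corrected only by the
  half-Cauchy prior ratio. This breaks the funnel-shaped dependence between
  a random-effect sd and its effects that plain Gibbs mixes through slowly;
  without it roughly one fit in twenty showed Rhat ≈ 1.2 on a σ parameter
  at short chain lengths, with it all fits sit below 1.03.

Defaults: 2 chains, 5,000 burn-in, 20,000 further iterations thinned by 20
(2 × 1,000 = 2,000 retained draws; the retained count is configurable —
analyses elsewhere have reported 3,000-draw versions of the same settings,
and both counts are supported). Chains start from overdispersed random
points (per-chain init sd 1 and 2). Convergence is checked with the plain
(non-split) two-chain Gelman–Rubin statistic on **all** parameters,
threshold 1.1; a violation flags the result and warns, never silently
discards it. ψ is clipped to [1e-10, 1−1e-10] only inside Pearson
residuals, to keep the discrepancy finite for extreme draws.

**Summaries and diagnostics.** Effect size = posterior median; confidence =
95% HPD (shortest contiguous window containing ⌈0.95·n⌉ sorted draws, n ≥
20 required); direction = fraction of draws above zero. The Bayesian
p-value compares Σ(y−ψ)²/(ψ(1−ψ)) on observed versus same-draw replicated
outcomes. maxTSS scans thresholds 0…1 in steps of 0.001 ("all possible
thresholds" discretized; the grid is finer than any realistic gap between
predicted probabilities) and returns the smallest maximizing threshold.
Cross-validation splits are stratified by outcome so both classes appear in
every evaluation set; prediction uses posterior-median parameters, group
levels unseen in training effectively predict at the population mean
(their posterior median is prior-centered at 0), and missing test cells are
filled with the imputation-model median. The Wilcoxon rank-sum test uses
midrank ties, exact enumeration of all rank assignments when both groups
have ≤ 10 values, and the tie- and continuity-corrected normal
approximation otherwise.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the real analysis, not its
geography: climate bands are fixed low-order spatial gradients plus
smoothed Gaussian noise (deterministic under a seed; with zero noise each
band equals its gradient formula exactly); a virtual species occupies the
pixels whose scores fall inside a known Gaussian niche ellipse (so the true
envelope is analytic and envelope estimators can be scored against it);
outcomes are drawn from the establishment model itself, with covariates
from log-normal/normal distributions and effect sizes that default to
study-like values — ~80% baseline success, ~979 events, a positive niche
and propagule-size effect, a negative range-area effect, 10% MCAR
missingness on life-history columns, and a site mix placing roughly
two-thirds of releases inside the focal species' range.

Passing tests on these data demonstrate that the estimators recover known
truth under the model's own assumptions. They do not demonstrate
robustness to what real data add: spatially autocorrelated and non-Gaussian
niches, biased range maps, phylogenetic correlation beyond the
species/family hierarchy, non-MCAR missingness, or errors in historical
outcome records.

Problem sizes used by the shipped checks are deliberately desk-scale: the
acceptance script runs 979 events across 48 species on a 60×120 grid with
2 × 1,000 retained draws, and the sampler-calibration suite uses 20
datasets of n = 1,000 with 2 × 500 retained draws; all sizes are
configuration values, and the full-scale defaults (5,000/20,000/20 MCMC
settings) remain the package defaults.

## Known limitations

- Envelope contouring is 2-D only; higher-dimensional work must use
  ellipsoidal envelopes with the k-D distance utility.
- Raster I/O reads multi-band TIFF with an embedded/sidecar JSON grid
  description and assumes WGS84 lon/lat; there is no CRS reprojection and
  no ESRI shapefile reader (ranges are GeoJSON).
- The realized-niche KDE inherits range-map coarseness: rasterizing expert
  range maps at fine resolution can attach climates the species never
  occupies (the aggregation utility exists for exactly this sensitivity
  check).
- The Wilcoxon exact branch enumerates C(n1+n2, n1) assignments and is
  restricted to both groups ≤ 10 by design.
- P[effect>0] for a truly null coefficient is approximately uniform on
  (0,1) across datasets (it is Φ of an approximately standard-normal
  z-score), so single-dataset "directional probability near 0.5" checks
  are weak evidence of anything; coverage of HPD intervals across many
  replicates is the meaningful calibration check and is what the
  recovery suite measures.
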