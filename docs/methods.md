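# Methods

This note records the models, the parameter choices that matter, what the
synthetic generator does and does not emulate, and the numerical decisions —
in enough detail that a maintainer can judge what a passing test suite shows.

## Solar geometry and threshold geolocation

Declination and the equation of time use the standard low-precision
trigonometric series in day-of-year (NOAA formulas). Both the twilight
simulator and the position estimator call the same functions, so noise-free
round trips close to solver precision and any bias in the series cancels.

A dawn/dusk pair yields one position. Longitude is
`15·(12 − midpoint_UTC − EoT/60)` degrees. Latitude solves

    cos H = (sin h₀ − sin φ sin δ) / (cos φ cos δ)

for φ by bisection on [−85°, 85°] (64 steps), where 2H is the observed
twilight-to-twilight arc, δ the declination and h₀ the sun elevation
corresponding to the light threshold. Day length is monotone in latitude for
δ ≠ 0, so the root is unique when it exists; when the bracket has no sign
change (equinoctial geometry) or the root sits against the search boundary,
the fix is flagged `latitude_indeterminate` and only longitude is kept.

The sun elevation matching a light threshold of 20 on these loggers is not
observable from the data we generate; it is fixed at **−3.0°** and used
identically on both sides of the round trip. Filters use the stated settings:
minimum dark span 4 h, equinox windows ±20 d (boundary inclusive; equinox
dates are computed per year from the declination zero-crossings, giving
20 March and 22/23 September), and a speed filter whose threshold is the 95th
percentile of the per-bird maximum travel speeds across the processed cohort
(the per-bird maximum itself when only one bird is available). The filter
iteratively flags the single worst fix by forward/backward-averaged speed and
recomputes; it is idempotent, and all filters only set flags — raw rows are
never mutated, so provenance survives the whole pipeline.

Phenology: departure is the first date outside a 200 km colony radius
(≈ one geolocation error unit) followed by three consecutive days of
increasing colony distance; arrival mirrors it. When no positional arrival
exists — typically because the return falls in the March equinox window —
the first post-trip night whose 22:00–04:00 UTC immersion block is entirely
dry is used instead (colony attendance is nocturnal and the burrow is dry),
and the result is tagged `arrival_method="immersion"`. Days whose maximum
light never reaches the threshold can be dropped up front
(`drop_dark_days`): that is our operationalization of excluding incubation
shifts spent in a dark burrow.

## Space use and clustering

Utilization distributions are isotropic Gaussian KDEs in geographic degrees
on a 0.25° grid, with the reference bandwidth
`sqrt(0.5 (var_lon + var_lat)) · n^(−1/6)` — the convention of the
home-range literature for unprojected coordinates. Working in degrees
distorts east–west distances away from the equator; the study region spans
roughly 35°S–37°N, so the distortion is modest and identical to the cited
default behaviour we mirror. The 5% isopleth is the smallest cell set
holding 5% of mass (cells in decreasing density order); its centroid is
**density-weighted** — whether the original procedure weighted by density or
used the plain polygon centroid is not stated, and for the compact core
regions involved the two differ by less than a grid cell.

PAM is the classical BUILD + greedy-best SWAP on the haversine distance
matrix (R = 6371 km); ties break to the lowest index so runs are
deterministic, and tests verify exact agreement with brute-force enumeration
for all n ≤ 8, k = 2 instances. Silhouette widths are computed from the
distance matrix directly (singleton clusters score 0, matching the common
convention) and cross-checked against scikit-learn. The k search range is
2..10: the cited selection routine starts at 2, so k = 1 is never
considered.

## Isotope statistics

δ-notation: `(R_sample/R_standard − 1)·1000` ‰. LDA is stored in
classification-function form — coefficient vector Σ⁻¹μ_g and constant
−½μ_gᵀΣ⁻¹μ_g + ln π_g per class, pooled covariance divisor n − g, equal
priors. Equal priors add identical constants to every class, so they cancel
in comparisons; the printed single-decimal display is formatting only, full
precision is stored. Score ties assign the first class with a warning.

The 70/30 split first places one random record per bird in training (all
remaining records, including a bird's repeats, go to testing) and then, per
class, moves random training records to testing until the class's test share
reaches 30% — per class rather than overall, because the reported validation
table is per class. The model is fitted once, after the final split.
Classification totals are sample-size-weighted means of per-class rates.

Group comparisons: one-way ANOVA with Tukey HSD letters for data passing a
per-group Shapiro–Wilk check (α = 0.05), otherwise Kruskal–Wallis
(tie-corrected) with Dunn's post-hoc z-tests, Bonferroni-corrected, at
α = 0.05. Letters come from the insert-and-absorb compact-letter algorithm;
groups sharing no letter differ.

Standard ellipse areas: SEA = π√(λ₁λ₂) from the sample covariance
eigenvalues, SEAc = SEA·(n−1)/(n−2). The Bayesian variant draws covariances
from a conjugate normal–inverse-Wishart posterior (ν₀ = 3, prior scale
0.01 × sample covariance, prior mean at the sample mean) and maps each draw
to an SEA. This replaces a Gibbs-sampled implementation and is not
numerically identical to it; with vague priors both concentrate on the
sample covariance.

## Isoscapes

Empirical semivariograms bin half squared differences into 12 equal-width
lags; the spherical model γ(h) = c₀ + c(1.5 h/a − 0.5 (h/a)³) (flat beyond
a) is fitted by least squares weighted by pair counts, with nonnegativity
bounds. A flat or non-converging table falls back to (nugget 0, sill =
mean semivariance, range = max lag/2) with a warning — the GIS auto-fit we
mirror is opaque, so all three parameters are logged on every run. Ordinary
kriging solves the augmented system with a Lagrange multiplier (LU-factored
once, all grid cells solved in one batch); weights sum to 1 by construction
and predictions are exact at data points when the nugget is 0. Duplicate
point locations are averaged with a warning. Distances default to planar
degrees — the convention of grid GIS kriging on geographic data — with a
haversine-km mode available; the prediction grid is 1° and the mask is the
union of 4° planar buffers around the centroids. The Mollweide transform
(Newton solve of 2θ + sin 2θ = π sin φ) is equal-area for rendering;
analysis values are never projected.

## What the generator emulates — and what it does not

The generator reproduces the *statistical* structure the estimators assume:
four colonies at their true coordinates and breeding windows with cohort
shares proportional to the recovered-logger counts (7/45/15/19); a 21/86
South Atlantic share; scripted departures after the breeding window;
great-circle migration legs capped at 1000 km/day (well above real petrel
speeds, configurable); ≥ 150 days of residency as a mean-reverting wander
clipped inside the area box, with anchor points clustered near the box
centre so the centroid field forms two compact clouds as observed; twilight
times from true solar geometry plus independent Gaussian noise (2 min SD by
default, which yields ~90 km median position error, inside the tags'
reported 186 ± 114 km); immersion counts in 0..200 with colony nights dry;
and feather values drawn from bivariate normals at the published
per-feather/per-area means and SDs, P1 from the bird's colony class and
S8/R6 from its area class. The δ¹⁵N–δ¹³C correlation within a class is
unreported and defaults to 0 (exposed as a parameter).

It does **not** emulate: behaviourally realistic movement (no correlated
random walks or state switching), raw lux curves (twilight times are
emitted directly, so light-curve artefacts like shading are outside scope),
weather- or habitat-driven twilight error structure (real geolocator error
is heavier-tailed and spatially correlated than independent Gaussian
minutes), annual variation in isotope baselines, or within-individual moult
variability. Passing tests therefore demonstrate that the estimators invert
the assumed data-generating process correctly at the study's design and
noise scale — not that the field data satisfy those assumptions.

The Central/South boundary used by the original clustering is not published;
the boxes here (Central 40°W–15°W × 5°S–20°N, South 40°W–5°E × 35°S–15°S)
are emulation choices matching the mapped centroid clouds, and are
configurable.

## Problem sizes and determinism

Every generator and experiment is a pure function of (configuration, seed);
the pipeline manifest records SHA-256 digests of all artifacts and identical
configs reproduce identical digests. The validation suite runs the study
design at full size where it is cheap (86 centroids × 100 replicates for
cluster-count recovery; 100 seeded 70/30 splits; 100 seeded kriging runs on
a 1° grid) and uses 5-bird cohorts for the geolocation round-trip summaries,
which already yield ~800 clean fixes per condition.

## Known limitations

- The bisection latitude solver returns the unique physical root but flags
  rather than resolves near-equinox geometry; no state-space smoothing is
  attempted (out of scope by design).
- Compact-letter displays are not unique in general; the insert-and-absorb
  construction is the standard one but other valid letterings exist.
- The kriging system is solved densely; for hundreds of points this is
  instant, but the implementation is not meant for thousands of support
  points.
- Classification-function coefficients are reported to one decimal for
  display parity with the published form; rounding the coefficients before
  scoring can flip assignments within ~0.05 ‰ of the decision boundary, so
  scoring always uses full precision.
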