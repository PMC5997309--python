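# isoflight

Light-level geolocation and feather stable-isotope assignment for oceanic
seabirds, built around the Atlantic Bulwer's petrel (*Bulweria bulwerii*)
system: birds from four Macaronesian colonies (Vila, M. Clara, Raso, Cima)
winter in either the Central or the South Atlantic, and the δ¹⁵N/δ¹³C values
of feathers grown in those waters carry enough of the regional baseline
signal to assign individual birds to their non-breeding area without a
tracking device.

The package is aimed at movement ecologists who want a fully scripted,
testable version of this inference chain — from raw twilight/immersion series
to clustered non-breeding areas, discriminant assignment functions, isotopic
niche ellipses and kriged feather isoscapes — plus a synthetic-data generator
that reproduces the study design so every stage can be exercised without any
field data.

## The analysis chain

1. **Threshold geolocation** (`isoflight.geolocation`). Twilights are
   detected where light crosses a fixed threshold (20). Longitude comes from
   the offset of the dawn–dusk midpoint from apparent solar noon (equation of
   time applied); latitude from day length given the solar declination.
   Transitions with dark spans < 4 h, dates within ±20 d of an equinox, and
   fixes above the cohort's 95th-percentile maximum travel speed
   (iterative forward/backward-averaging filter) are flagged, never deleted.
   Departure/arrival dates come from colony distance with a directed-movement
   rule, falling back to the "dry all night ⇒ in the burrow" immersion rule.
2. **Space use** (`isoflight.space_use`). Per bird, a Gaussian-kernel
   utilization distribution (reference bandwidth *h*) is reduced to the
   centroid of its 5% isopleth; centroids are clustered by partitioning
   around medoids (PAM) on the great-circle distance matrix, with *k* chosen
   by the maximal overall average silhouette width over k = 2..10.
3. **Isotope assignment** (`isoflight.isotopes`). Linear discriminant
   analysis in classification-function form with equal priors: class *g*
   scores x = (δ¹⁵N, δ¹³C) with

       f_g(x) = (Σ⁻¹μ_g)·x − ½ μ_gᵀΣ⁻¹μ_g + ln π_g

   (Σ = pooled within-class covariance, divisor n − g) and a bird is
   assigned to the class with the larger score. A 70/30 train/test protocol
   with at most one record per bird in training guards against
   pseudo-replication. Group contrasts use ANOVA + Tukey HSD or
   Kruskal–Wallis + Dunn with compact-letter displays; isotopic niche width
   uses standard ellipse areas (SEA, SEAc, and conjugate-posterior draws).
4. **Isoscapes** (`isoflight.isoscape`). Ordinary kriging of the per-centroid
   feather values with a spherical semivariogram fitted by weighted least
   squares, masked to a 4° buffer around the centroids, written as ESRI
   ASCII grids (Mollweide transform available for rendering).
5. **Synthetic data** (`isoflight.synthetic`). Colony metadata, two
   non-breeding boxes, speed-capped scripted migrations, solar-consistent
   twilights, burrow-dry immersion nights, and bivariate-normal feather
   classes at the published per-feather/per-area means and SDs.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a simulated
86-bird cohort (seed 1) and write their tables under `results/run/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_geolocate.py
python analysis/03_cluster_nonbreeding_areas.py
python analysis/04_assign_with_isotopes.py
python analysis/05_krige_isoscapes.py
```

Stage 2 reports `19707 daily positions, 28.0% flagged` and that 27 of 86
arrivals needed the immersion rule (their positional return fell in an
equinox window). Stage 3 prints

```
silhouette-selected k = 2 (mean width 0.842)
86 centroids; cluster label matches simulated area for 100.0%
```

i.e. the silhouette criterion recovers exactly two non-breeding clusters and
every bird lands in its true one. Stage 4 prints the fitted classification
functions and the per-feather area contrasts — P1 (grown early, in the
shared Central Atlantic corridor) shows no area difference (δ¹⁵N ANOVA
F = 2.61, p = 0.110), while S8 and R6 (grown after settlement) separate
strongly (e.g. R6 δ¹³C F = 67.7, p < 1e-11, distinct letters) — and the
ellipse table (e.g. R6 South SEAc = 2.65 ‰²  vs Central 1.39 ‰²). Stage 5
summarizes the kriged surfaces:

```
S8 d15N: Central +12.90  South +14.65
R6 d13C: Central -16.51  South -17.34
```

— the South Atlantic surface is enriched in δ¹⁵N and depleted in δ¹³C for
both late-moulted feathers, the gradient the assignment relies on.

The same pipeline is scriptable in one step (`isoflight run-all --seed 1
--out results/run`) or from a TOML config.

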