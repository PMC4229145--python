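# Methods

## The system being modeled

Oak mistletoe is a long-lived hemiparasite on blue and valley oaks whose
berries are the key winter food of group-territorial western bluebirds.
Because the birds both consume and plant the seeds, abundance of mistletoe
may be spatially autocorrelated at the scale of persistent territories.
`mistlemap` separates two questions with two families of statistics:

* is the *amount* of mistletoe (a continuous mark, log-volume per tree)
  autocorrelated, and over what distance? — variogram + permutation test;
* are the *trees bearing mistletoe* (a point pattern) aggregated, and up to
  what distance? — Ripley's K and O-ring against a CSR null restricted to
  the oak habitat polygon.

## Volume model

Clump counts per tree in six size categories are valued as sphere volumes
(4/3)πr³ with representative radii 10, 20, 35, 60, 75 cm for categories
1–5.  Category 6 holds elongate clumps, valued as k sphere volumes of the
largest class; k defaults to 2 and is overridable per run.  The survey
protocol states the representative sizes as radii and the package follows
that statement verbatim, although the field bin labels (diameters <20 cm …
1–1.5 m) would also admit a mid-diameter reading; users with their own
calibration can supply a custom `ClumpSizeScheme`.  The spatial mark is the
**natural** logarithm of total volume — the transform's base is a free
choice that rescales nugget and sill but not the range; it is recorded in
output metadata (`log_base: e`).  Trees with zero recorded volume carry no
mark: geostatistical stages operate on the marked subset, point-pattern
stages on all trees.

The proxy analysis (female, fruit-bearing volume vs total volume) reports
Pearson r, r², and F = r²(n−2)/(1−r²) on (1, n−2) df; the identity is
asserted in tests for every computed result.

## Variogram estimation and fitting

The empirical semivariogram is the classical method-of-moments estimator on
distance bins of width 25 m (default) up to 1,000 m (default); both are
exposed on the CLI since survey-scale choices are legitimate tuning.  The
spherical model is fitted by deterministic multi-start bounded least
squares.  The default objective is Cressie's relative criterion
Σ N_k (γ̂_k/γ(h_k;θ) − 1)², which downweights bins in proportion to the
(approximate) variance of γ̂; plain N_k weighting and OLS are available.
A noiseless variogram is inverted to the generating parameters to ≤ 1e-6
(test-asserted); an exactly flat variogram returns a pure-nugget model with
the range tie-broken to the maximum distance, with a warning.

The permutation test re-assigns marks over fixed locations B = 1000 times
(default) and takes pointwise (α/2, 1−α/2) percentiles per bin.  Pair
distances and bin assignments are computed once and reused across
permutations, so B = 1000 at n ≈ 2,700 (≈ 3.5 M pairs) runs in seconds.
Under iid marks the per-bin escape rate is close to α but the all-bins
verdict is not α-calibrated, because bins are dependent; the type-I test in
the suite therefore checks per-bin escape rates against exact binomial
acceptance regions rather than the joint rate.

## Gaussian random field generator

Marks are drawn from a multivariate normal whose off-diagonal covariance is
the structured part c·ρ(h) of the spherical model
(ρ(h) = 1 − 1.5h/a + 0.5(h/a)³ for h < a, 0 beyond) and whose diagonal is
c₀ + c: the nugget is independent per tree and never shared, so duplicate
coordinates stay valid (their covariance is c).  The dense covariance is
Cholesky-factorized with additive jitter 1e-8·(c₀+c); this is exact at desk
scale (n ≤ ~5,000, the study's n = 2,658 factorizes in ~2 s) and preferred
over spectral approximation.  Non-positive-definite matrices after jitter
raise an error.

## Parameter-recovery experiment

`experiments.variogram_parameter_recovery` simulates 2,658 CSR trees in a
2,646 × 2,646 m window (700 ha), draws marks at nugget 2.4, partial sill
0.79, range 250.3 m, and refits.  Medians over 20 seeds recover the range
and nugget to within a few percent and the partial sill — the noisiest of
the three, being the small difference between sill and nugget — to within
~10%.  This is the package's core validation: the full estimation path
(binning, weighting, optimization) is unwound against known truth at the
study's own scale.  One seed costs ~1 s; the 20-seed experiment a few
minutes.

Note a deliberate asymmetry: the recovery experiment uses the *continuous*
GRF marks, while the pipeline's `volume` stage recomputes marks from the
decomposed clump counts.  Count decomposition quantizes volumes downward
(by up to one category-1 sphere) and trees below one category-1 volume have
no recordable clumps at all, so a refit on count-derived marks shows a
smaller sill than the generating field — visible in the README example.
That is field realism, not estimator bias.

## Ordinary kriging

Per grid cell, the ordinary-kriging system with the semivariance matrix of
the k = 64 nearest data (global solve available for small n by raising k)
and the Lagrange unbiasedness row is solved directly.  γ(0) = 0 by
convention — the nugget applies for any h > 0 — so the predictor honors
data exactly at data locations; a singular system is retried with a small
diagonal jitter before erroring.  Predictions are written as an ESRI ASCII
grid.

## Point-pattern statistics

**Ripley's K** uses by default the uncorrected estimator
K̂(r) = |A|/(n(n−1)) Σ 1(d_ij ≤ r).  No analytic edge correction is applied
because the testing logic is design-based: the identical estimator (the
same function object, asserted in tests) is applied to the observed pattern
and to every CSR simulation in the same window, so the boundary deficit
cancels in the envelope comparison.  The deficit itself is not small — for
CSR in a square of side L, E[K̂(r)] = πr² − 8r³/(3L) + r⁴/(2L²) exactly
(≈ 8% below πr² at r = L/10), and the suite verifies the estimator against
this closed form.  An experimental translation correction
(rectangular windows only) is provided where an unbiased K̂ is needed, e.g.
for comparison against the analytic πr² or against the O-ring derivative.

**O-ring** is the ratio estimator
Ô(r) = Σ_i n_i(annulus r ± w/2) / Σ_i area(annulus_i ∩ region), with
annulus∩region areas obtained by counting square grid cells whose centers
fall in both; it is edge-corrected by construction and ≈ λ under CSR.  The
published protocol states a "cell size of 6.2 m²"; the package reads this
as a cell *side* in meters (default 6.2 m) since a square of area 6.2 m²
(side 2.49 m) is not expressible in the software the protocol names, and
documents the ambiguity here.  Ring width defaults to 18.6 m, the distance
grid to 40 equal steps to 724 m.  Grid discretization error of the annulus
area is O(cell/ring width); the interior-annulus estimate is verified
against 2πrw to 2% at the default-scale ratio.

**Envelopes** use the k-th lowest/highest of n_sim simulated curves
(defaults k = 5, n_sim = 199 ⇒ pointwise level 2k/(n_sim+1) = 5%).  Null
points are placed by bounding-box rejection sampling inside the habitat
polygon — the user-supplied oak-vegetation layer when available, else the
convex hull of the observed trees.  Departure intervals are maximal runs of
above/below verdicts with endpoints linearly interpolated to the envelope
crossing between adjacent grid distances.

## Synthetic-data generator: what it does and does not emulate

Defaults reproduce the printed study descriptors: a 2,646 × 2,646 m square
(700 ha) window, 2,658 trees, the published variogram parameters, mean
log-volume 10 (arbitrary; only differences matter to the variogram), 25
territories, 82 dispersal records.  Choices made where the study gives no
generative detail:

* **Aggregation** — a Thomas cluster process (Poisson parents at 2e-5 /m²,
  ~19 offspring each, 50 m Gaussian displacement), the minimal standard
  cluster model; parents may sit outside the window, offspring are rejected
  outside, and the pattern is truncated to the exact tree count after a
  shuffle.  The CSR branch is the null the study itself simulates.
* **Female volume** — female_i = clamp(s·total_i + ε, 0, total_i) with
  s = 0.5 and ε ~ N(0, 120,000 cm³), calibrated by simulation so the sample
  correlation at n = 45 averages ≈ 0.90.
* **Territories** — centers ≥ 250 m apart, 15 census points uniform in a
  158 m disc; the disc radius is calibrated so the mean 15-point MCP area
  approximates 41,663 m² (a k-point hull covers only part of its generating
  disc, hence radius > the 115 m equivalent radius).
* **Dispersal** — a two-component half-normal mixture (30% at scale 130 m,
  70% at scale 439 m) solved so that P(d < 250 m) ≈ 0.585; it implies
  P(d < 900 m) ≈ 0.97.  The real kernel's shape is unknown; only these
  quantile targets are emulated.

The generator does not emulate: inhomogeneous habitat quality, oak stand
structure or host-size effects on mistletoe load, measurement error in
clump classification, or mechanistic seed transport.  Passing tests
therefore demonstrate correctness of the *estimators* under the stated
stochastic models, not ecological validity of those models for any real
landscape.

All randomness flows through one explicitly passed `numpy` generator; the
pipeline splits a single global seed into independent per-stage streams via
`SeedSequence(seed, spawn_key=(stage_index,))`, so identical configurations
are byte-reproducible and disabling one stage leaves the others' draws
unchanged.

## Numerical choices and degenerate inputs

* Pair binning: bin k spans [k·w, (k+1)·w); a pair exactly at the maximum
  distance lands in the last bin; zero-distance pairs are excluded from the
  variogram (γ(0) = 0 by convention).
* Fitting bounds: c₀, c ≥ 0, a > 0; ties across multi-starts resolve to the
  first (fixed) start order.
* Collinear census points give a zero-area MCP with a warning, not an
  error; a single territory reports no standard error.
* Dispersal thresholds compare strictly (`d < t`); a flagged long-distance
  outlier can be excluded from all summaries by mask.
* Coordinates are planar meters throughout; readers refuse input whose
  coordinates all fit within |x| ≤ 180, |y| ≤ 90 as probable lon/lat.

## Problem sizes used in the test suite

Simulation-backed checks run at reduced but informative sizes chosen as the
smallest where the asymptotic behavior being tested is visible: estimator
oracles at n = 400–500 in a 1 km square with 40–100 replicates, the
permutation-size study at n = 500 with B = 199 over 200 replicates, and the
parameter-recovery experiment at the full study scale (n = 2,658, 20
seeds).  The whole suite completes in about a minute on one CPU.

## Known limitations

* Isotropic spherical variograms and ordinary kriging only — no anisotropy,
  alternative model families, or trend (universal) kriging.
* Homogeneous-Poisson nulls only; no inhomogeneous-intensity K.
* The translation edge correction is limited to axis-aligned rectangles and
  flagged experimental.
* The O-ring grid is anchored at the region's bounding-box corner; a
  different anchoring convention would perturb estimates at the
  discretization-error level.
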