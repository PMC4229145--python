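# mistlemap

Spatial analysis of oak-mistletoe (*Phoradendron villosum*) abundance in oak
savanna, built for ecologists asking whether a keystone winter fruit resource
is spatially structured at the scale of the territorial birds that disperse
its seeds.  The package provides, as a tested and reusable pipeline:

* **Clump-volume quantification** — field crews score mistletoe clumps into
  six size categories; categories 1–5 are valued as spheres of radius 10,
  20, 35, 60 and 75 cm, category 6 (elongate clumps) as k ≥ 2 largest-class
  sphere volumes.  Per-tree volume is the count-weighted sum and the spatial
  mark is z = ln(volume).
* **Variogram inference** — the empirical semivariogram
  γ̂(h) = 1/(2N_h) Σ (z_i − z_j)², a spherical model
  γ(h) = c₀ + c·(1.5 h/a − 0.5 (h/a)³) for h ≤ a (sill c₀ + c beyond the
  range a) fitted by weighted least squares, and a permutation test that
  re-assigns marks over fixed tree locations to bracket the
  no-autocorrelation null with a pointwise envelope.
* **Ordinary kriging** of log-volume onto a regular grid from the fitted
  model (k-nearest-neighbor systems with the unbiasedness constraint
  Σλ = 1).
* **Point-pattern tests** — Ripley's K(r) and the O-ring statistic O(r)
  with Monte Carlo envelopes under complete spatial randomness (CSR)
  restricted to the oak-habitat polygon: the observed pattern's point count
  is re-thrown uniformly in the region n_sim times and the k-th extreme
  simulated values form the envelope (5th extremes of 199 simulations ⇒ a
  95% envelope), plus detection of the distance intervals where the
  observed statistic departs it.
* **Territory geometry** — minimum-convex-polygon (MCP) areas from winter
  census points, the equivalent circular radius r = √(A/π), and natal
  dispersal-distance summaries.
* **A synthetic-data generator** that emulates the study system (aggregated
  tree patterns via a Thomas process, Gaussian-random-field log-volume
  marks with a spherical variogram, calibrated territories and dispersal
  kernels), so every stage is testable without the unreleased field data.

## Worked example

```bash
mistlemap simulate --out data --seed 4                       # 2,658 trees, 700 ha
mistlemap volume    --trees data/trees.csv --out data/trees_vol.csv
mistlemap variogram --trees data/trees_vol.csv --out vg --perms 199 --seed 4
mistlemap territory --census data/territories.csv
mistlemap dispersal --records data/dispersal.csv
```

prints

```
wrote synthetic dataset (2658 trees) to data
wrote data/trees_vol.csv
spherical fit: nugget=1.88 partial_sill=0.391 range=273.7 m; autocorrelation evidence: True
n=25 mean area=39965 m² equivalent radius=112.8 m
n=82 dispersal fractions <250 m: 57.3%, <900 m: 95.1%
```

Reading the output: the fitted variogram **range** (273.7 m here) is the
distance beyond which log-volume marks are uncorrelated — the generator's
range is 250.3 m, and the permutation envelope flags the autocorrelation as
real (`evidence: True`).  The fitted sill is smaller than the generating one
because the `volume` stage rebuilds volumes from the *recorded clump counts*,
which quantizes the continuous field (see `docs/methods.md`).  Mean winter
territory area ≈ 40,000 m² corresponds to an equivalent circular radius of
≈ 113 m, and ~57% of natal dispersal distances fall within 250 m — one
territory diameter — which is the behavioral scale the variogram range is
compared against.  `mistlemap krige` and `mistlemap ppa` produce the kriged
abundance surface (ESRI ASCII grid) and the K / O-ring CSR-envelope tables;
`mistlemap all --config cfg.yaml` runs every stage and writes a manifest.

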