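# Methods

## Model and procedure

`karstprior` scores caves on four criteria (nTS, TbS, EnD, VuL), converts
the scores to category weights, aggregates them onto a rectangular grid by
per-attribute maxima, sums the four layers into a composite conservation
value (PiC) per cell, and classifies occupied cells into priority tiers by
exact natural breaks. The method assumes:

- coordinates are planar meters in a projected system, so Euclidean
  distance is adequate at landscape scale (no geodesy);
- impacts are point sites — polygonal land uses must be rasterized to
  points upstream;
- the troglobiont/non-troglobiont status of every species is an input flag
  (taxonomic determination is outside the package);
- caves are the sampling units for richness estimation.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| `bbox` | (0, 0, 40 000, 30 000) | m | a 1200 km² landscape extent |
| `ncols × nrows` | 40 × 30 | cells | 1200 cells of exactly 1 km² |
| `buffer_radius_m` | 250 | m | vulnerability buffer around each cave; boundary inclusive |
| `weights` | 100/250/500/1000 | score | Low→Extreme category weights; must increase strictly with rank |
| `tbs_extreme_min` | 7 | species | minimum troglobiont richness for the Extreme class |
| `end_zero_policy` | `table_literal` | — | EnD = 0 maps to Low (100); the `zero` policy maps it to absence (0) |
| `n_classes` | 4 | — | natural-breaks priority tiers |

Two conventions are fixed deliberately rather than left to the reader:

- **Buffer boundary inclusive** (distance ≤ radius): "within a buffer"
  naturally includes its boundary, and an explicit rule is needed for
  reproducibility.
- **Grid cells half-open** on their upper/right edges, with the last
  column/row closed, so every point of the bbox belongs to exactly one
  cell, including the far corner.

A note on cell size: 1200 cells tiling 1200 km² makes each cell 1 km²
(10⁶ m²). Cell dimensions are always derived from the bbox and grid shape,
never hard-coded.

### nTS binning

Non-troglobite richness is binned by four equal-width integer intervals
recomputed from each dataset's observed min/max
(`u_i = floor(vmin + i·(vmax−vmin)/k)`); over an observed range of 17–93
this yields the class bounds 17–36 / 37–55 / 56–74 / 75–93. Recomputing
per dataset keeps the scheme portable: the bounds are a property of the
data, not universal constants. The remaining three criteria use fixed
small-count bins (see README) because their values are bounded by
construction (EnD ≤ TbS, VuL ≤ 5).

### Natural breaks

The classifier is the exact Fisher dynamic program: minimal total
within-class sum of squared deviations over contiguous partitions of the
sorted values. Two reproducibility choices:

- the DP runs over **unique values with multiplicities**, so ties always
  share a class and the classification is a pure function of value;
- among equal-cost optima the **lexicographically smallest** break-position
  vector is chosen, via suffix-DP reconstruction that always takes the
  earliest feasible break.

Classification runs on occupied cells only. Including the ~1100 empty
cells would put nearly all mass at zero and collapse the classes into
"zero vs everything else", destroying the tiers the method is meant to
produce. Fewer distinct PiC values than classes is a contract error, not a
silent degradation.

### Jackknife completeness

The first-order incidence-based jackknife
`S_jack1 = S_obs + Q1·(n−1)/n` is the canonical closed form for the named
estimator. With S_obs = 32, Q1 = 21, n = 105 it gives 52.8 and a
completeness of 32/52.8 ≈ 0.606. Published summaries of comparable surveys
sometimes quote a higher completeness for these same counts; no choice of
the estimator's inputs consistent with those counts reproduces such a
figure, so the package reports the closed-form value and documents the
divergence rather than reconciling it.

## The synthetic landscape generator

The generator emulates the statistical structure the analysis assumes in
its source data, so every stage is testable without field data:

- 105 caves over a 40 × 30 km extent, half placed in 6 Gaussian clusters
  (σ = 1.5 km) and half uniformly — karst caves cluster along outcrops;
- lognormal cave lengths with target mean 102.7 m (σ = 0.9 on the log
  scale, a typical right-skew for cave surveys);
- non-troglobite richness ~ round(Normal(49.2, 17.1)) clipped to [17, 93];
- a 32-species troglobiont pool with 65.6% single-cave endemics; wider
  species get occupancy from a truncated power law over 2–10 caves with
  cave choice weighted by length, inducing the positive length–richness
  association such surveys report (only the sign of the association is
  targeted);
- seasons assigned as 49 dry / 54 wet with any remainder labelled unknown;
- per-cave impact sites: the number of distinct types follows
  (0.32, 0.57, 0.08, 0.03) for 1–4 types — mirroring a reported
  34/59/9/3 vulnerability-class split of 105 caves — with type identities
  drawn from the mix 54% agriculture/forestry, 18% pasture, 15% mining,
  7% urbanization, 6% paved roads (pasture carries the residual share).
  Sites are placed 20–240 m from their cave, so every cave is guaranteed
  ≥1 impact within the 250 m buffer.

A single seed drives all randomness through per-component substreams;
identical parameters give byte-identical CSV output. The truth record
stores planted per-cave nTS/TbS/EnD, the planted impact-type count, and
the global singleton count. Planted nTS/TbS/EnD are exact oracles for the
attribute computations; the planted impact count is only a lower bound on
computed VuL, because a site planted for one cave can legitimately fall
within 250 m of a clustered neighbour.

What the generator does **not** emulate: real species composition or
spatial autocorrelation of communities, polygonal land uses, geological
structure, or detection error in sampling. Passing tests therefore show
the pipeline's arithmetic and classification behave as specified on data
with the right marginal structure — not that the scheme is ecologically
validated on any real landscape.

`plant_hotspot` adds one maximal-profile cave (richness at the dataset
maximum, 7 troglobionts, exactly 2 new single-cave endemics, 4 impact
types) at a chosen cell; its score vector is (1000, 1000, 500, 1000) and
its cell reaches the attainable composite maximum of 3500, which must land
in the top natural-breaks class — the package's end-to-end recovery check,
run across 20 seeded landscapes in the suite.

## Numerical choices and degenerate inputs

- All scores are integers; PiC ∈ [0, 4000], and ≤ 3500 whenever no cave
  has 3+ stenoendemics.
- Equal-interval binning requires `vmax − vmin ≥ k − 1`; a value outside
  the built range is an error instructing the caller to rebuild intervals
  (they are dataset-scoped, never reused across datasets).
- The Jenks DP uses prefix sums; reconstruction compares float costs for
  exact equality against the DP table (same expressions, same rounding),
  with an argmin fallback.
- Validation is total: inputs load fully or fail with a located error;
  rows are never silently dropped (duplicate occurrence pairs can be
  explicitly deduplicated by option).
- Pipeline failures remove partial artifacts and name the failed stage.

## Problem sizes

The test suite and acceptance script run on landscapes of 105 caves /
1200 cells, 100-seed calibration sweeps, 120-replicate subsampling
experiments, and 500-instance brute-force cross-checks of the Jenks DP
(n ≤ 12, k ≤ 4) — sizes chosen so the full suite completes in well under a
minute while the brute-force oracles remain exhaustive.

## Known limitations

- Only point impacts; no raster or polygon land-cover support, no CRS
  transformations, no shapefile/GeoPackage IO (GeoJSON + CSV only).
- Only the additive weighting scheme with a configurable category→weight
  map; no multi-criteria decision analysis beyond it.
- Only the first-order jackknife; no Chao, bootstrap, or rarefaction.
- The priority map inherits every bias of the underlying inventory:
  unsurveyed caves contribute nothing, and cells without caves are
  unclassified rather than "low priority".
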