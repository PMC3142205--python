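# Methods

## The accessibility model

`fcaccess` measures *potential spatial accessibility* — how much clinic
supply a resident could reach, given where clinics are and where people
live — with the two-step floating catchment area (2SFCA) method.

**Step 1.** Every supply site `j` gets a supply-to-demand ratio over the
demand inside its catchment, the set of demand zones whose centroid lies
within a travel threshold `d0` (closed inequality, `d <= d0`):

    conventional:  R_j = 1000 * S_j / Σ_{k : d_kj <= d0} D_k
    optimized:     R_j = 1000 * P_j / Σ_{k : d_kj <= d0} W_k

`S_j` is the site's unit capacity (1 clinic by default), `P_j` its
physician count, `D_k` the zone's population, and `W_k` its *potential
users*: the age-structured population weighted by past-year
clinic-utilization proportions,

    W_k = Σ_x c_x · P_x

over nine age bins (0-14, 15-19, …, 80+). The packaged utilization
schedules (Montreal, Quebec, Canada; 2005-2006 survey estimates) supply
the `c_x`. `W_k` is kept fractional.

**Step 2.** Every demand zone `i` sums the ratios of the sites inside its
own catchment: `A_i = Σ_{j : d_ij <= d0} R_j`. `A_i` is in supply units
per 1,000 persons — clinics per 1,000 for the conventional method,
physicians per 1,000 potential users for the optimized one.

This is the *binary-catchment* 2SFCA: no distance decay within the
catchment (the enhanced/gravity variants are out of scope). When a
consistent demand-by-supply distance matrix is used for both steps and
every site's catchment is populated, the method conserves total supply:
`Σ_i D_i·A_i / 1000 = Σ_j S_j` (and the `W/P` analogue) — a property the
test suite asserts to 1e-9 relative error.

### Missingness conventions

* A site with no demand in its catchment has an **undefined** ratio
  (logged as a warning); it contributes nothing at step 2. We deliberately
  avoid an infinite ratio.
* A zone with no site in its catchment has a **missing** score (NaN), not
  zero. Summaries report `N` = number of defined scores, which therefore
  grows with the threshold.
* Both steps use the same threshold by default; differing thresholds
  require an explicit override flag.

## Distances

Distances are planar meters. Two metrics are provided:

* **Euclidean** between zone centroids and clinic points.
* **Network shortest path** (Dijkstra) on an undirected street graph with
  positive edge lengths. Points snap to the single nearest network node,
  ties broken by lowest node id; the point-to-node access hop is *not*
  added by default (a flag adds the Euclidean hop at both ends).
  Unreachable pairs get `+inf` and fall outside every catchment.

Zone centroids are taken as supplied — geometric or population-weighted,
the package does not care; the choice is the data producer's and affects
aggregation error. Geographic (lon/lat) layers are rejected at the reader
level via the `crs_units` metadata field.

## Comparing the two methods

Scores from both methods are min-max rescaled to [0, 100] *within the
zones where both are defined* (rescaling requires range > 0 and at least
two values) and differenced:

    D_i = rescaled_conventional_i − rescaled_optimized_i

Negative `D` means the conventional method under-estimates accessibility
relative to the optimized one. The apparatus around `D`:

* **Spearman's rho** (average ranks, two-sided p via the t
  approximation) between the raw score vectors.
* **t-test**: default is a one-sample test of `mean(D) = 0`, because one
  mean and one p-value per threshold is what the difference table
  reports. A Welch two-sample mode comparing the rescaled vectors is also
  provided; the two agree in sign. Zero-variance `D` with nonzero mean
  reports `t = ±inf, p = 0`.
* **Percentile table** of `D` (5/10/25/50/75/90/95, linear
  interpolation — the same convention as all summaries here).

## Spatial statistics

**Moran's I** in its classic raw-weight form,

    I = (n / S0) Σ_ij w_ij (y_i − ȳ)(y_j − ȳ) / Σ_i (y_i − ȳ)²,

with `E[I] = −1/(n−1)` and, by default, the closed-form variance under the
normality assumption (randomization variance available as an option);
z-scores and two-sided normal p-values. Weight matrices: binary **queen
contiguity** (polygons sharing any boundary point, corner included;
computed geometrically with an optional buffer tolerance for dirty data)
and **inverse distance squared** (`w_ij = 1/d_ij²`, zero diagonal,
coincident centroids are an error naming the pair). Weights are used raw;
row standardization is an explicit transform. When `D` is defined on a
subset of zones, the weight matrix is subset accordingly before the
statistic is computed.

**Centrography** of the clinic pattern: physician-weighted mean center;
weighted standard deviational ellipse using dof-uncorrected second
moments (the classic GIS convention), reported with the major semi-axis
first and its angle from east; and the Clark-Evans **nearest-neighbour
index** `NNI = d̄_obs / (0.5·√(A/n))` with `SE = 0.26136/√(n²/A)` and a
two-sided p. The study area `A` is a modelling choice and must normally
be supplied; a convex-hull fallback warns loudly. `NNI < 1` indicates
clustering; a unit lattice gives exactly 2.0.

## The synthetic city

The generator builds instances on which every pipeline stage is testable
offline: a `rows × cols` tessellation of square zones (`cell_size`
meters), a connected grid street network, and clinics drawn as a mixture
of a Gaussian around the city center (fraction `clinic_clustering`, sd
`cbd_sigma_frac` of the city diagonal) and a uniform scatter. Per-zone
totals are lognormal; the age mix is Dirichlet around a fixed packaged
profile; physician counts are `1 + Poisson(λ)`. One seed drives
everything through independent `numpy` substreams, so adding a component
never perturbs the others and equal seeds give byte-identical output.

The `montreal_like` preset emulates the study conditions of a large
island city: 56×56 = 3,136 zones of 400 m (≈ the zone size implied by
483 km² over ~3,100 census zones), 236 clinics with physician mean
1344/236 ≈ 5.7, per-zone lognormal totals with median 542 and log-sd
0.395 (so mean/median ≈ 586/542), and an age profile whose
Montreal-schedule user share is ≈ 0.772 (observed population mean ≈ 586,
potential users ≈ 453). The `dense_small` preset is a 600 m city where
every clinic has demand and every zone has access at 500 m, used for
conservation checks; `toy9` is a 9-zone smoke instance.

What the generator does *not* emulate: real census geography (zones are
equal-area squares), spatially correlated age structure, multi-center
cities, anisotropic street networks, and edge effects from supply outside
the study region. Passing tests therefore demonstrate the correctness and
qualitative behaviour of the methods, not quantitative agreement with any
particular real city.

## Numerical choices

* Catchment threshold is inclusive (`d <= d0`).
* Percentiles: linear interpolation between order statistics throughout;
  SD is the sample (ddof = 1) estimator.
* Per-1,000 scaling applied at step 1, so step 2 is a plain sum.
* Equality of the vectorized engine with a literal double-loop
  transcription is asserted to 1e-12 relative tolerance on random
  instances; Moran's I likewise against a direct double sum.
* Problem sizes in tests and in the acceptance run: the full pipeline is
  exercised on the 3,136-zone preset; oracle-equivalence sweeps use ≤ 15
  clinics × ≤ 60 zones, where a quadratic loop is exact and instant.

## Known limitations

* Binary catchments: a clinic 10 m outside `d0` contributes nothing.
* No edge-effect correction: supply outside the study area is ignored
  (zones near the boundary are biased low); the package flags, not fixes.
* Travel impedance is distance, not time; one-way streets and turn
  restrictions are not modelled.
* The NNI significance is the classic Clark-Evans normal approximation,
  which ignores boundary effects on nearest-neighbour distances.
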