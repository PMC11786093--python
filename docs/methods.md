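# Methods

This note documents the models, defaults and numerical choices behind
`greenhia`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Exposure pipeline

Each city-year starts from a stack of 16-day-style NDVI scenes on a fine
planar grid (nominally 250 m) with a binary QA flag per pixel, and ends as
one population-weighted and one unweighted zonal NDVI value.

Order of operations:

1. **QA masking** — pixels flagged invalid become nodata.
2. **Range filtering** — values outside the plausible vegetated-surface
   range become nodata. The inequalities are strict (NDVI < −0.2 or
   NDVI > 1.0), so the boundary values −0.2 and 1.0 are retained. QA and
   range filtering both only set nodata, so they commute; the order is
   fixed for reproducibility, not by necessity.
3. **Median compositing** — per-pixel median of the year's valid
   observations; even counts use the midpoint of the two central values;
   a pixel is nodata only when it has no valid observation.
4. **Temporal consistency** — per pixel, across the annual composites, a
   value is invalid when it departs from the cross-year median by more
   than a threshold (default 0.3 NDVI, configurable). The screen operates
   on the annual series because a "sudden, uncharacteristic change" is a
   between-year phenomenon; it needs at least 3 valid years, otherwise
   the series passes unscreened and a warning is counted.
5. **Water masking** — water pixels become nodata, since blue space may
   carry an independent health effect and must not count as greenness.
6. **Grid alignment** — NDVI is block-averaged (mean of valid fine pixels
   per k×k block) onto the coarse population grid, and the weighting is
   done at population resolution. The alternative — downscaling
   population to 250 m — would require inventing a within-cell population
   model; block-averaging NDVI conserves population mass exactly and
   keeps the weighting faithful to where the population data actually
   live. Grids must share an origin and differ by an exact integer pixel
   ratio; anything else is an error, never a silent resample.
7. **Zonal statistics** — a pixel belongs to a city iff its centre lies
   inside the polygon (centre-point rule, the reproducible convention for
   per-pixel zonal sums). Pixels with nodata NDVI are excluded from both
   the numerator and denominator of the weighted mean. A city-year whose
   valid member pixels carry zero population has no defined exposure; it
   is excluded and logged rather than imputed.

The summer-mean variant (June–August arithmetic mean instead of the annual
median) exists for sensitivity analysis and runs through the same
downstream machinery.

## Trends

Ordinary least squares of exposure on centred survey year, with a
two-sided t-test on the slope at n − 2 degrees of freedom. With the
default five quinquennial survey years this is a 3-df test — deliberately
fragile, so nothing assumes asymptotics. Classification is
Increase/Decrease only when p < 0.05 strictly; a tie at p = 0.05 is "No
change". Degenerate conventions: a constant series has slope 0 and p = 1;
an exactly-fit nonzero slope has p = 0; a series whose spread is at
rounding-error level (ptp ≤ 1e−12 of scale) is treated as constant, so
floating-point jitter in an otherwise flat exposure series cannot
manufacture a significant trend.

## Health impact equations

Relative risk rescales log-linearly from the per-increment anchor
(RR = 0.96 per +0.1 NDVI, 95% CI 0.94–0.97): RR(Δ) = RR₀.₁^(Δ/0.1), which
is algebraically identical to exp((ln RR₀.₁/0.1)·Δ). Both forms are
implemented and cross-checked to 1e−12. AF = (RR−1)/RR and
M = y₀·Pop₂₀₊·AF, kept unrounded internally; presentation rounding is
half-away-from-zero at output only.

Scenario pairing: the 2000–2010 change and the 2000 counterfactual use the
2000 adult population and y₀ = 5.5‰; the 2010–2020 change and the 2010
counterfactual use the 2010 adult population and y₀ = 4.3‰. The
counterfactual target is the linear-interpolation 75th percentile of the
same year's city-level weighted NDVI distribution, computed over all
cities.

Counterfactual totalling: cities already at or above the target have a
negative (no-benefit) signed value. Per-city tables report that signed
value, but provincial/regional/national counterfactual totals clip each
city's contribution at zero — the counterfactual question is how many
deaths lifting the below-target cities would prevent, not a net transfer.
Change-scenario totals are never clipped.

Aggregation sums city-level unrounded values city → province → region →
national, each level in sorted-unit order, so conservation along that
roll-up is exact in floating point. Municipality-level units are a
province containing a single leaf city, counted once. Greenness rankings
break ties by unit id so they are deterministic permutations.

## Monte Carlo uncertainty

Each iteration draws three independent sources:

- **ERF**: log-normal on the per-increment RR, mean ln 0.96,
  sd = (ln 0.97 − ln 0.94)/(2·1.96) ≈ 0.0080. The published CI is
  asymmetric around 0.96 on the log scale, so the implied quantiles are
  (0.945, 0.975), not the printed bounds themselves.
- **NDVI delta**: normal around the observed delta, default sd 0.02 NDVI.
- **Population**: normal around the observed adult population with
  default CV 5%, with negative draws set to zero (immaterial at that CV).

All draws come from standard-normal bases scaled by the requested spreads
(common random numbers), so widening one spread can only widen the
interval and a fixed seed reproduces everything bit for bit. The point
estimate is the deterministic central computation, never a draw average.
Regional intervals perturb city deltas and populations independently but
share one ERF draw per iteration across all cities; national draws are the
per-iteration sum of regional draws, preserving the correlation the shared
ERF induces. Whether the ERF draw should be shared or independent across
units is a genuine modelling choice; sharing is the conservative one
(wider national intervals) and the `vary` machinery makes the alternative
a one-line change.

Variance decomposition is one-at-a-time: each source is varied alone and
its draw variance reported as a share of the all-sources-on variance
(shares need not sum to 1; the remainder is interaction). Variances below
(1e−9·|M|)² are treated as exactly zero so a constant draw vector does not
report spurious shares. With the defaults above, the delta is the dominant
source for typical city deltas; note that the ERF's contribution exceeds
the population's unless the population CV is raised well above 5%.

## Synthetic data: what it emulates, what it does not

The generator builds per-city tiles on a flat planar grid (unit CRS):
convex urban-extent polygons, fine-grid NDVI scene stacks with QA
dropouts (default 10% per scene), injected out-of-range outliers (default
1%), fixed water pixels (default 5%), and coarse population grids (integer
block ratio 4, mirroring 250 m vs 1 km) with a Gaussian centre–periphery
density gradient scaled to a city total between ~50 k and ~2 M that grows
up to 3%/yr. True NDVI trajectories are linear in year and spatially
uniform within a city, with i.i.d. Gaussian scene noise (default sd 0.02);
the default trend mix is 60% increasing / 10% decreasing / 30% flat with
|slope| in 0.001–0.006 NDVI/yr, reflecting a study period in which
greening dominates and significant declines are rare. The Gaussian noise
model is a convenience choice — the error distribution of real composites
is not documented — and spatial uniformity is what makes the true exposure
analytically known.

Consequences for validation: passing tests show that the pipeline recovers
known exposures, trends and death counts exactly on clean inputs and
degrades sensibly under contamination. They do not show that the pipeline
handles real-composite artefacts the generator omits: phenology curves,
spatially correlated cloud and error fields, realistic census age pyramids
(the adult population is total × a single fraction, default 0.75),
multi-part urban extents, or geodesy (no reprojection; the analysis is
per-pixel areal weighting, which a planar grid exercises fully).

Baseline mortality by survey year bridges the two anchors linearly
(5.5‰ in 2000 to 4.3‰ in 2010) and holds flat afterwards; only the 2000
and 2010 values enter the four scenarios.

## Problem sizes and numerics

The validation suite runs the full study shape — 390 cities at 64×64 NDVI
pixels each for the clean-recovery checks, 100 cities for brute-force
per-pixel oracle comparisons, 10,000 Monte Carlo draws at region level,
2,000 replicates for interval-coverage calibration — chosen to match the
assessment's own scale while keeping a complete run in minutes on one
core. Tolerances: exact equality where the arithmetic is exact (printed
table roll-ups, conservation along the roll-up order, the ERF anchor),
1e−12 for formula-equivalence and oracle identities, 1e−9 relative (on a
scale of y₀·Pop, the deaths at AF = 1) for parameter recovery, ±1.5
percentage points around 95% for Monte Carlo coverage.

Grids are stored as a self-describing plain-text format carrying the same
header fields a single-band GeoTIFF would (width, height, origin, pixel
size, nodata) plus year/month/kind metadata; values round-trip exactly via
17-significant-digit decimal. City polygons are GeoJSON FeatureCollections
with a fixed seven-region vocabulary validated on read.

## Known limitations

- Ecological design: city-level aggregation, no individual confounders.
- The ERF is a single all-cause, all-adult relative risk; no
  cause-specific or age-stratified effects, no lag structure.
- OLS trends assume stability; structural breaks in rapidly urbanising
  cities will be misfit (a documented limitation of the linear model).
- The per-city deaths in counterfactual scenarios are sensitive to the
  percentile target's discreteness for cities near the target.
- Real QA bit-field decoding is out of scope; the QA layer is a binary
  validity flag.
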