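# Methods

This note documents the model behind `auklet`, the choices made where the
procedure was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Assessment model

The pipeline compares two decadal windows of weekly gridded ocean-projection
slices — a recent baseline (calendar years 2003–2012) and a future window
(2030–2039) — for a small ensemble of model realizations (three by default)
and five variables: seawater temperature (SWT, °C), sea ice cover (% ice
fraction area), large copepods and euphausiids (mg C/m³), and benthic
infauna (mg C/m²).

**Temporal aggregation.** Per-cell period means are equal-weight arithmetic
means over the weekly slices whose timestamps fall in the period and season
window.  Seasons are defined by calendar month: winter Dec–Feb, spring
Mar–May, summer Jun–Aug, fall Sep–Nov; December of year Y counts toward the
winter beginning in year Y.  "Annual" averages every slice in the period
directly rather than averaging the four seasonal means, so seasons with
slightly different slice counts are weighted by slice, not equally.

**Depth classes.** The grid carries ten vertical layers spanning 0–200 m.
Two classes aggregate the water column by thickness-weighted layer means:
shallow (0–60 m) and deep (75–200 m).  A layer belongs to a class only if
its interval is contained in the class window, so a layer straddling the
60–75 m gap belongs to neither — the gap between the classes is deliberate
and layer-aligned.  Sea ice is surface-only and benthic infauna bottom-only;
neither has a depth class.  Sea-ice fields are clipped to a
maximum-ice-extent mask before any statistics.

**The SD change value.** For a unit (region or core area), variable and
model,

    sd_change = (mu_t2 − mu_t1) / SD_t1

where mu_t1 and mu_t2 are the unit's recent- and future-period means and
SD_t1 is the spatial standard deviation of the recent period-mean field over
the reference cells.  At regional scale the reference is the region polygon
itself (all cells whose centers fall inside it); at core-area scale it is a
moving window of the nearest 2500 data cells from the core-area centroid
(Euclidean cell-center distance, ties broken lexicographically by
(distance, row, col) for cross-platform determinism).  All SDs use the
population divisor n: the reference SD describes the region's own spread,
and at window sizes near 2500 the n vs n−1 distinction is negligible; fixing
it makes tests exact.

**Classification.** Vulnerability thresholds act on the adverse-direction
scale (decrease adverse for ice and forage, increase adverse for SWT):
adverse < 0.1 SD → low, 0.1–1 SD → moderate, ≥ 1 SD → high.  The 0.1-SD cut
is the prey-abundance change point associated with declining seabird
breeding success ("one-third for the birds"); 1 SD flags a shift outside
the central range of baseline variability on a < 40-year horizon.
Classification is applied to unrounded values, and the boundaries are
closed on the adverse side (adverse = 0.1 is moderate, adverse = 1.0 is
high), making the three categories a partition of the reals.

**Cross-model roll-up.** Per unit × variable: *agreement count* = number of
models classifying the unit moderate-or-high; *magnitude* = mean SD change
across models; *magnitude-agreement (M-A) score* = magnitude × (agreement
count / number of models), classified on the same thresholds.  At group
level (Large Marine Ecosystem, ecoregion, species set): % vulnerable counts
units vulnerable under ≥ 1 model; the agreement fraction is the summed
agreement count over (units × models); group M-A score = group mean
magnitude × agreement fraction.  These definitions make |M-A| ≤ |magnitude|
with equality exactly at full agreement, and M-A = 0 whenever no model
flags the unit.

**Core-area orchestration.** Core areas are single-species polygons with a
guild, an occupancy season and a parent IBA.  Areas are retained when their
extent exceeds 300 km² and every depth class *available* to them (≥ 1 data
cell of that class inside the area's bounding rectangle) has at least 3 data
cells there; deep SWT is then assessed exactly where the deep class is
available.  Cell extraction uses the axis-aligned minimum bounding rectangle
in grid space with cell-center membership — deliberately including cells
inside the rectangle but outside the polygon.  Variables are matched per
species: SWT annually for everyone; sea ice with spring data and only for
areas intersecting the ice-extent mask (spring ice concentration governs
productivity of the ice-free season); forage variables from the foraging
table at the area's occupancy season.  Species whose only primary prey is
fish/cephalopods have no assessable forage variable and are excluded.  Each
area is attached to the Large Marine Ecosystem (and ecoregion) with the
largest polygon-intersection area, ties broken toward the smaller region id.

## Synthetic-data generator

The generator produces the study conditions the analysis assumes: three
pseudo-model realizations, two decadal periods of 52 weekly slices per year
(520 per period; the weekly cadence is model-defined, not calendar-weeks),
a 10 × 10 km grid with ten depth layers, the five variables above with
their physical units, divergent per-model injected trends, core-area
polygons on both sides of the 300 km² filter with all four occupancy
seasons, a northern-half ice-extent mask, and a species × prey foraging
table spanning planktivore / benthos-feeder / mixed / fish-only diet
archetypes.

Baseline spatial fields are Gaussian-kernel-smoothed white noise
(correlation length 50 km by default ≈ five cells) affinely standardized to
an exact target mean and population SD, so the reference-region SD is
nontrivial and known.  The future period adds a grid-wide shift of
`injected_change_sd × spatial_sd`; temporal noise is i.i.d. per slice and
cell (default SD = 10% of the spatial SD); an optional seasonal sinusoid
defaults to amplitude 0 so unit-test expectations stay closed-form.
Physical clamps (ice ∈ [0, 100], biomass ≥ 0) are applied after noise so
bounds hold in the output; default baselines sit far enough from the bounds
that clamping is inactive and recovery stays unbiased.  Every stochastic
draw derives from recorded seeds, and identical (spec, manifest, seed)
inputs reproduce outputs bit-for-bit.

With 520 slices per period, the per-cell temporal sampling error of a
period mean is `0.1·SD/√520 ≈ 0.004·SD`, which is why an injected change of
k SDs is recovered by the full pipeline well within the ±0.05 tolerance the
tests assert.

What the generator does *not* emulate: ocean dynamics, advection, cold-pool
structure, bathymetry-driven missingness, realistic coastlines or
geographic coordinate systems, inter-annual trends within a period, or
cross-variable correlation.  Passing tests therefore demonstrate that the
statistics and orchestration are computed correctly under the stated
assumptions — not that the pipeline's ecological conclusions transfer to
any real model ensemble.

## Numerical and formatting choices

- Geometry lives entirely in the grid's projected plane (km); cell (0, 0)
  at the origin corner, centers at origin + (index + 0.5)·cell size.
- Missing data are NaN with an accompanying boolean mask; every statistic
  skips missing cells, and an aggregate cell is missing only where all
  contributing slices/layers are missing.  Per-cell depth weights
  renormalize over non-missing layers.
- All stored values keep full precision; display tables round half-up to
  two decimals with a sign, rendering magnitudes in (0, 0.005) as "<+0.01"
  (and (−0.005, 0) as ">−0.01") rather than a misleading 0.00.
- Grids are written as NetCDF (classic format via the SciPy backend) with
  float32 payloads; round-trips are exact to float32 representation.
  Regions travel as GeoJSON, tables as UTF-8 CSV.
- A degenerate reference (zero spatial SD) is a loud error at the
  `sd_change` step, not a silent NaN.

## Problem sizes used by the test suite

Chosen so the default run exercises every code path at meaningful scale:
moving-window/oracle equivalence on 200 random 100×100 grids; parameter
recovery for k ∈ {−1, −0.5, 0.5, 1} through the full pipeline on a 100×100
grid × 3 pseudo-models × 520 slices/period (bottom-only variable), plus a
30×30 layered-variable recovery across k ∈ {−1, …, 1}; end-to-end CLI
determinism on a 12×12 grid with 8 core areas; classification totality on
10⁵ random values.  The CLI demo default is a 20×20 grid with 12 areas.

## Known limitations

- Point estimates only: no uncertainty propagation or confidence intervals
  on SD-change values, and a three-member ensemble bounds what "agreement"
  can mean.
- Decadal averaging smooths out extreme events and sub-seasonal phenology
  (e.g. ice-retreat timing), which may matter more to seabirds than mean
  change.
- The bounding-rectangle extraction rule can dilute or inflate a
  non-convex area's signal with cells it does not actually occupy.
- Group M-A scores are recomputable from their printed inputs only when
  magnitude and agreement are themselves internally consistent; the package
  always applies the stated definition (magnitude × agreement).
- Fish and cephalopod forage is carried in the foraging table but never
  assessed (no projected variable exists for it), so "vulnerable for all
  variables assessed" excludes the dominant prey of many piscivores.
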