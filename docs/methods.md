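# Methods

`smokewave` implements the analysis chain for a short wildfire-smoke PM2.5
episode: a 2×2 factorial ensemble of gridded daily-mean concentration fields
is averaged and decomposed into emissions- and meteorology-attributable
uncertainty; the fields are scored against monitor observations; the
episode-mean concentration change relative to a no-wildfire control is
aggregated to counties and pushed through a log-linear health impact
function to yield attributable events and incidence rate ratios (IRRs); and
modeled IRRs are compared against IRRs observed in emergency-department (ED)
visit count series. This note records the model, the choices that were
genuinely open, and what the synthetic test bed does and does not show.

## Factorial uncertainty decomposition

The ensemble varies two inputs at two levels each: wildfire emissions
inventory (CAMS, QFED) and meteorological driver (FNL, NAM). The reference
field is the cell-wise mean of the four wildfire-inclusive members (the
"ensemble average"). The factor contributions are signed half-sums of paired
member differences,

    emissions:    ½ [(QFED_FNL − CAMS_FNL) + (QFED_NAM − CAMS_NAM)]
    meteorology:  ½ [(CAMS_FNL − CAMS_NAM) + (QFED_FNL − QFED_NAM)]

which, for an ensemble with no emissions×meteorology interaction, recover
each factor's injected difference exactly and are blind to the other
factor's. The subtraction order (QFED minus CAMS, FNL minus NAM) is a
recorded constant, not a parameter — reversing it only flips signs.
Relative uncertainty is 100 × absolute / ensemble-average per cell. Cells
whose ensemble average falls at or below a floor (default 1 µg m⁻³) are
masked as undefined rather than reported, to avoid unbounded percentages
over clean-air cells; the floor is configurable. Tabular reports round
half-away-from-zero to one decimal; internal arithmetic is full precision.

## Model evaluation

Monitor-days are joined to the grid cell whose center is nearest the
monitor; no interpolation is performed, and out-of-domain monitors are
skipped with a log entry. Pooled over all site-days:

    MB = mean(model − obs)             RMSE = √mean((model − obs)²)
    NME = 100 Σ|model − obs| / Σobs    NMB = 100 Σ(model − obs) / Σobs

Slope, intercept and R² come from OLS of model (ordinate) on observation
(abscissa); with a degenerate (constant) cloud the regression is reported as
NaN rather than a fabricated zero. Nearest-center lookup and the regression
orientation are conventions: nothing in the statistic battery depends on
them being the only defensible choice, and per-site breakdowns are
available.

## Health impact core

For county i with population Pop_i and baseline incidence rate y0_i
(events per person-day), an exposure change Δx_i (µg m⁻³, episode mean
over n days) and a concentration–response coefficient β (per µg m⁻³):

    ΔY_i = y0_i · Pop_i · (1 − e^(−β·Δx_i)) · n
    baseline events_i = y0_i · Pop_i · n

Storing y0 per person-day and multiplying by the episode length is an
explicit convention; it makes the 3-day default window and any other window
commensurable. Δx is the crosswalk-weighted cell mean of
(scenario − control), with the control the mean of the two no-wildfire runs
(single-control mode available); crosswalk weights are supplied, validated
to sum to 1 per county, and never derived from polygons here. The variance
of ΔY propagates SE(β) by the delta method,

    Var(ΔY_i) = (y0_i · Pop_i · Δx_i · e^(−β·Δx_i) · n)² · SE(β)²,

with a seeded Monte-Carlo mode (β ~ Normal(β, SE)) as a cross-check; the
two agree within 5% whenever SE(β)·Δx < 0.05, which covers every default
scenario. Aggregated over any county grouping,

    IRR = ΣΔY / Σbaseline events + 1
    CI95(events) = ΣΔY ± 1.96 √(ΣVar)
    IRR CI = [CI_lower/Σbaseline + 1, CI_upper/Σbaseline + 1].

Because only sums enter, partitioning counties into regions and
re-aggregating is exact. Endpoint coefficients (asthma ED visits,
respiratory ED visits, cardiovascular hospital admissions, work-loss days)
ship as a configurable registry; the bundled values are synthetic defaults
for exercising the pipeline, not published coefficients, and the registry
accepts either county-specific or national baseline rates.

## Observed IRR and validation

For a region's daily ED-visit counts, the observed IRR is the ratio of mean
daily visits on smoke-wave days to mean daily visits on baseline days, with
a 95% CI from the Poisson rate-ratio approximation on the log scale,
exp(log IRR ± 1.96·√(1/Σsmoke + 1/Σbaseline)). The interval method is
documented and swappable; nothing downstream depends on it beyond the CI
bounds. The default baseline window is 7 days before and 7 days after the
episode with a 3-day buffer excluded on each side — all three lengths are
parameters. The comparison step reports, per region, both IRRs, both CIs,
and whether the intervals intersect, plus the fraction of regions with
overlapping CIs.

## Synthetic test bed

The generator produces every input with known ground truth: a smooth
background (8 ± 2 µg m⁻³) plus a 2-D Gaussian plume (core 180 µg m⁻³,
width 5 cells) advecting across a 40×50 grid of 12 km cells over 3 days.
Emissions variants scale the plume amplitude (CAMS 0.85, QFED 1.15, a ±15%
spread, so switching inventories moves core concentrations by tens of
µg m⁻³, ~30% of the ensemble average); meteorology variants offset the
trajectory by 2 cells. These magnitudes emulate a severe smoke wave in
which daily means exceed 100 µg m⁻³ over a populated area. Monitors (30
sites) observe a truth field with Normal(0, 5 µg m⁻³) noise truncated at
zero. Counties tile the grid in 5×5 blocks with equal cell weights and
log-uniform populations in [5×10⁴, 2×10⁶]; y0 = 2.2×10⁻⁵ per person-day.
The default β = ln(1/0.6)/100 ≈ 5.108×10⁻³ per µg m⁻³ is the value for
which Δx = 100 µg m⁻³ yields a modeled IRR of 1.40, a realistic severe-
episode magnitude; SE(β) = 5×10⁻⁴. ED-visit counts are Poisson with daily
rate y0 · Pop · e^(β·Δx_day), zero exposure on baseline days. All outputs
are deterministic given the config seed (independent substreams per output).

What the test bed does not emulate: correlated meteorology, chemistry,
plume-rise, spatially structured monitor error, county-shape realism,
overdispersed visit counts, or day-of-week visit structure. Passing tests
therefore demonstrate the correctness of the arithmetic chain under the
stated model, not skill against real smoke episodes.

### The IRR round trip and its exposure-metric sensitivity

The end-to-end check simulates visit counts from the same β used for
modeling and asks whether the modeled study-area IRR falls inside the
observed-IRR 95% CI across 20 seeded replicates (each with ≥ 500 baseline
visits). Two IRR forms meet in this comparison: the count-generating rate
scales baseline visits by e^(β·Δx), while the modeled IRR is
2 − e^(−β·Δx̄); they agree to first order in β·Δx and differ at second
order. In the round trip the smoke-day exposure fed to the count simulator
is the model's own episode-mean Δx per county, held constant across the
smoke days: this holds the exposure metric fixed so the check probes the
exposure-aggregation → health-function → IRR chain itself. Feeding
day-varying exposures instead adds a Jensen-inequality inflation of the
observed rate (counties that see the plume core for a single day contribute
e^(β·Δx_day) ≫ e^(β·Δx̄)); with that variant and per-region pooling the
measured coverage sits just below 0.9 — a property of the exposure-metric
mismatch, not of the IRR arithmetic, and worth knowing when comparing
multi-day-average health functions against daily administrative counts.

## Numerical choices and degenerate inputs

* Rounding for printed percent columns is decimal half-away-from-zero at
  one decimal (`round_half_up`), applied only at reporting time.
* Relative change at sub-floor averages is NaN plus an explicit mask, never
  silently zero.
* An incomplete factorial raises an error naming the missing members; a
  crosswalk referencing off-grid cells, negative populations, negative
  weights, non-integer or negative visit counts, and overlapping
  smoke/baseline windows all fail fast with named offenders.
* Zero baseline events make IRR undefined and raise; a zero smoke-day total
  returns IRR 0 with an undefined upper bound rather than a fake interval.
* The observed-IRR CI and the Monte-Carlo variance mode are the only
  stochastic elements outside the generator; both take explicit seeds.

## Problem sizes

Default study conditions (40×50 grid, 3 days, 25 counties, 30 monitors,
20-replicate round trip) run the full suite and the acceptance script in a
few minutes on a single CPU; the structural tests use a scaled-down 20×30
grid where the property under test is size-independent.

## What cannot be recomputed here

The published evaluation statistics, county IRR rankings, and observed New
York IRRs for the June 2023 episode require the original chemical-transport
model outputs, the regulatory monitor records, and restricted
administrative health (ED-visit) records; none are bundled or downloadable
by this package, so those numbers cannot be reproduced here. The pipeline
substitutes property-based guarantees on synthetic data with known ground
truth — exact decomposition recovery, oracle-matched statistics, health-core
identities, and the IRR round trip — as its acceptance surface.
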