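# Methods

This note documents the model implemented in `ecoshift`, the reasoning
behind the open design choices, and what the synthetic test systems do and
do not demonstrate.

## Model structure

The domain is a set of polygonal boxes with a scalar alongshore coordinate
(`latitudinal_axis`); "northward" means increasing values.  The water
column is collapsed to a single layer per box; the maximum-depth class of
each box is retained as a static attribute used by distribution priors and
fleet footprints.  The domain is closed: no biomass crosses the outer
boundary, which is consistent with distribution forcing that sums to one
over the domain.

Three kinds of functional group are supported:

* **Producers** grow logistically, `dB/dt = ts · r · B (1 − B/K)`, with a
  per-box carrying capacity `K` (tonnes) and the light-saturated rate `r`
  (per day) scaled by the Q10 factor `ts`.
* **Pools** (zooplankton and similar) carry one biomass per box.  They can
  consume, and they die through a linear rate plus a quadratic closure
  (below).
* **Age-structured groups** carry numbers per box for 10 age bins of
  configurable breadth (`years_per_bin`) and a single coastwide mean weight
  per bin.  One weight per bin is not a simplification on top of the
  forcing scheme but forced by it: proportional redistribution of coastwide
  totals every timestep cannot preserve per-box weight structure, so boxes
  hold numbers only.

### Temperature

Forcing is either a recycled climatological year (the baseline: no
interannual variability, full seasonal and spatial structure) or the same
climatology plus additive per-year, per-box anomalies from a named source
("delta downscaling").  Anomalies are annual step changes applied at year
boundaries without sub-annual interpolation; the seasonal cycle shape is
preserved exactly.  Annual rather than monthly application is a choice, not
an inference about the reference implementations this emulates.

Biological rates respond through `ts = q10^((T − 15)/10)` with `q10 = 2`:
rates double per 10 °C above 15 °C.  The scalar is applied to maximum
ingestion, clearance, linear (unexplained) mortality, and producer growth.
It is deliberately **not** applied to the respiration coefficient: with
both intake and respiration scaled, the factor cancels from the weight
equilibrium and warming has no sustained effect on weight-at-age; with
respiration unscaled, warming raises the energy surplus and weight-at-age
whenever forage is sufficient, which is the bioenergetic behaviour this
model family is built to exhibit.  `grow()` retains a `t_scalar` argument
(default 1) for sensitivity experiments with scaled costs.  No growth
ceiling is imposed above thermal optima; over-prediction of weight under
strong warming is an acknowledged, deliberate limitation.

### Distribution forcing

SDM-forced groups follow time-ordered snapshots of per-box proportions
(annual, monthly, or seasonal cadence), linearly interpolated in time and
renormalized; queries outside the snapshot range use the nearest snapshot.
Linear interpolation is a documented choice; only "smooth movement between
steps" is required.  Before redistribution, knife-edge thermal tolerances
(default 4–30 °C) zero boxes outside the window and renormalize.  If the
window would exclude every box, the unmasked distribution is kept and a
warning is recorded — tolerances exist to prevent grossly wrong
distributions, not to extirpate groups.  Unforced groups are pinned to
their initial distribution, mirroring a mixed forced/unforced population.
Redistribution happens first in every timestep, before any trophic
resolution, and conserves coastwide numbers-at-age to floating-point
rounding.

### Consumption, growth, mortality

Consumption is Holling type II built from the two temperature-scaled
parameters, clearance `a` and maximum mass-specific ingestion `I_max`:

    intake of prey p per unit predator foraging biomass
        = ts · I_max · a·A_p·B_p / (I_max + a·Σ_q A_q·B_q)

where `A` combines the stage-resolved availability matrix with a
gape-window pass/fail on the prey/predator individual-weight ratio (closed
interval; pools expose a nominal individual weight).  *Foraging biomass* of
an age-structured predator is `N · w_ref` — ration anchors to the age
bin's reference size, while realized condition (`w/w_ref`) feeds back
through spawning.  This is deliberate: if per-individual ration scaled with
current weight, cohort weight would obey `dw/dt = w(εI − r)`, an
exponential knife-edge with no interior equilibrium; anchoring to `w_ref`
yields the stable fixed point `w* = (ε I φ / r) · w_ref`.  Age-class-level
ration parameterization is also how the full-scale models this emulates
are configured.

Mortality within a timestep is a single competing-risks exponential:
`N' = N exp(−(M_pred + F + ts·m) dt)`, with `M_pred` implied by summed
predator demand.  Because removals are `B(1 − e^{−Z dt})`, predation can
never exceed the biomass present; the shortfall factor
`(1 − e^{−Z dt})/(Z dt) ≤ 1` is returned and applied identically to every
predator's intake, which resolves multi-predator competition for one prey
proportionally and without order dependence.  Losses are attributed to
components by rate shares, and fleet catch is allocated within each box by
each fleet's share of the summed rate — so the catch ledger and the
fishing column of the mortality ledger are the same numbers by
construction.

Weight-at-age is advanced by explicit Euler:
`w' = w + dt(ε·intake_ind − r·w)`, floored at a starvation floor (default
50 % of `w_ref`, configurable).  When the floor binds, the ledger books the
clipped loss as reduced respiration so the mass-balance identity still
closes exactly.

Pools use the same machinery with one component; a quadratic closure
`m2 · B` (per day per tonne, not Q10-scaled) stands in for unresolved
predators.  A pure linear closure leaves the producer–grazer pair on a
Rosenzweig–MacArthur limit cycle at any parameterization rich enough to
feed the fish; the quadratic term is the standard plankton-model
stabilization and is booked in the "linear" ledger column.

### Recruitment and aging

Once per simulated year (at the last step of the year): spawning stock is
computed from the pre-aging population with a body-condition multiplier,
`S = Σ_a maturity_a · N_a · w_a · (w_a / w_ref,a)` (tonnes), recruits
follow Beverton–Holt `R = αS/(β + S)`, bins promote fractionally
(`1/years_per_bin` of each bin moves up; the last bin is a plus group;
promoted fish carry their weight, so receiving bins take the
numbers-weighted mean), and the new cohort then enters the vacated first
bin at `w_ref[0]`, distributed by the group's current distribution.
Computing spawning before aging and inserting recruits after it keeps the
first bin from being promoted in the year it was spawned.  Beverton–Holt
is a choice — only proportionality of spawning output to body condition is
structural; the stock–recruit form is not.

### Fisheries

Fleets are static for the whole run: a fixed footprint (explicit box set,
or every box whose polygon intersects a disc of given radius around a port,
evaluated in a local flat-earth projection) and fixed per-day harvest rates
per target group.  Non-spatial fleets cover the domain.  Overlapping fleets
are additive.  Fishing is applied continuously, with no seasons.  Realized
fishing mortality is diagnosed as catch over a window divided by mean
coastwide biomass times window length; it moves with spatial overlap even
though nominal rates never change.  `calibrate_harvest_rates` scales each
fleet's rate by `target/achieved` per iteration (clamped to [0.25, 4] per
step so the iteration cannot overshoot past surplus production and
collapse), preserving relative allocation among fleets sharing a target;
non-convergence is reported with residuals, not raised.

## Scenarios and metrics

The factorial crosses oceanography (baseline vs. projected from a cool,
mid, or warm delta source) with distributions (static initial-year vs.
time-varying), yielding Base, SpatialShift, Warming (mid source), and the
three combined runs.  Any scenario whose forcing and distributions are both
pinned to the initial year reproduces Base bit-for-bit; this is a tested
invariant, not an aspiration.  The runner is deterministic given (spec,
config, seed) — the seed only enters provenance, because all randomness
lives in synthetic input generation.  Non-finite state aborts a run with a
diagnostic snapshot; `run_all` isolates failures per scenario.

Contrasts are percent differences of end-of-window means (the final six
simulated years, i.e. 2095–2100 of a full-length run) against Base,
computed on raw timestep values.  Cells with a zero Base value are reported
missing, never infinite.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline needs: a sinusoidal
climatology whose mean falls with latitude and whose amplitude is larger
nearshore; linear warming ramps to 1.5/2.5/4.0 °C for the cool/mid/warm
sources (a CMIP5-era RCP8.5-like spread for an eastern-boundary upwelling
system); drifting-Gaussian distribution snapshots; toy food webs; and
port-based fleets.  The toy presets:

* `minimal` — 4 boxes, producer + pool + one forage fish, one southern
  fleet.  Demonstrates the catch/biomass decoupling mechanism.
* `cps_vs_dts` — 12 boxes, five groups contrasting a short-lived pelagic
  (annual bins, 10-year lifespan, strong poleward SDM) with a long-lived
  demersal (3-year bins, 30-year lifespan, weak SDM) under a northern
  piscivore and four fleets.  Used for the mechanism and mass-balance
  checks.
* `full_scale_structural` — 89 boxes (a 17 × 5 shelf grid plus four
  oceanic boxes), 90 groups, 10 age bins, 51 fleets (22 spatially
  resolved), SDMs for 42 groups.  Structure only: placeholder biology,
  never run for dynamical claims.

Both dynamic presets embed a deterministic baseline spin-up (50 and 80
years respectively) so scenario year zero starts at quasi-equilibrium;
age-structure transients from initialization have dissipated before any
contrast is measured.  Toy runs use 73 timesteps per year (5-day steps)
over 30–40 years for turnaround; the full 12-h/87-year protocol
(`timesteps_per_year = 730`) is carried by the structural preset.

Passing tests on these systems show that the *mechanisms* behave and
interact correctly — conservation, mass balance, the directional responses
(weight up under warming, old-age abundance down under combined shift and
warming, catch decoupling from biomass).  They do not show skill against
any real ecosystem: the synthetic webs have few groups, no biogeochemistry,
schematic geometry, and hand-chosen rates, so no numeric agreement with
any fully parameterized regional model is claimed or checked.

## Numerical choices

* Distribution snapshots must sum to 1 within 1e−9; redistribution inputs
  within 1e−6 (then renormalized exactly).  Conservation holds to ~1e−15
  relative and is tested at 1e−12.
* Mortality is exact exponential decay per step (unconditionally stable);
  growth and producer dynamics are explicit Euler at 5-day steps, which is
  well inside stability for the per-day rates used (all ≤ 0.8/day).
* Degenerate inputs: all-masked tolerance windows fall back to the
  unmasked distribution with a warning; zero-biomass groups interpolate,
  redistribute and decay harmlessly; zero spawning stock yields zero
  recruits; empty prey fields yield zero intake.
* Ties and floors: the gape window is a closed interval; the starvation
  floor binds before weights can reach zero; `realized_F` returns NaN on
  zero biomass rather than raising.

## Known limitations

No nutrient or oxygen cycling, no detritus web (a single closure term), no
larval dispersal or movement other than distribution forcing, no vertical
structure, no prey-quality variation, no effort dynamics or economics, and
no constraint on growth above thermal optima.  Salinity is carried in the
forcing types but ignored by the default tolerance masks.  These are scope
boundaries of the desk-scale design, not accidents.
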