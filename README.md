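# ecoshift

A desk-scale, end-to-end ecosystem scenario simulator for asking how climate
change reshapes a coastal upwelling food web and the fisheries that depend on
it.  Climate acts through exactly two channels, which can be switched on
independently and in combination:

1. **Warming** — per-box ocean temperature scales metabolic and trophic
   rates through an exponential Q10 factor; and
2. **Species redistribution** — externally supplied species distribution
   model (SDM) snapshots force how each group's coastwide biomass is spread
   across spatial boxes, drifting poleward over the century.

Spatially footprinted fishing fleets apply *static* harvest rates, so the
fishing mortality a stock actually experiences emerges from its shifting
overlap with fixed fishing grounds.  The package is aimed at ecosystem
modellers and fisheries scientists who want the mechanism structure of a
full end-to-end model (Atlantis-style: physics → plankton → age-structured
fish → fleets) at a scale that runs in seconds and is fully testable with
synthetic inputs.

## The model

State lives on a polygonal box geometry (GeoJSON) with a latitudinal axis
fixing "northward".  Functional groups are primary producers (logistic
growth toward a per-box carrying capacity), biomass pools (zooplankton,
with a quadratic closure), or age-structured populations (10 age bins,
numbers per box, one coastwide mean weight per bin).

Temperature enters every rate through the Q10 scalar

$$T_{scalar} = q_{10}^{(T_{water} - 15)/10}, \qquad q_{10} = 2.0,$$

applied to maximum ingestion, clearance, linear (unexplained) mortality and
producer growth: rates double for every 10 °C above the 15 °C reference.

Each timestep, in order: every group is redistributed proportionally to its
(interpolated, thermally masked) distribution; consumption is resolved as a
Holling type-II response on the availability- and gape-filtered prey field,

$$I_p = T_{scalar}\, I_{max} \frac{a A_p B_p}{I_{max} + a \sum_q A_q B_q},$$

mortality is applied as simultaneous competing exponential rates (predation
demand capped by the prey present, fishing from overlapping fleet
footprints, Q10-scaled linear mortality); and weight-at-age grows by
assimilated intake minus respiration.  Annually, Beverton–Holt recruitment
with a body-condition multiplier ($S = \sum_a m_a N_a w_a (w_a/w_{ref,a})$,
$R = \alpha S / (\beta + S)$) is followed by fractional age-bin promotion
with a plus group.  A per-step ledger makes mass balance an exact
bookkeeping identity.

Six scenarios form a two-factor design — oceanography (recycled baseline
year vs. projected warming from cool/mid/warm delta-downscaled sources) ×
distributions (pinned to the initial snapshot vs. time-varying SDMs):
Base, SpatialShift, Warming, and the three combined `<source>-SDMs` runs.
Results are compared as percent change in end-of-century means (final six
simulated years) relative to Base.

## Worked example

The `cps_vs_dts` preset is a 12-box shelf strip with a producer, a
zooplankton pool, a short-lived coastal-pelagic forage fish (annual age
bins, SDM shifting strongly poleward), a long-lived demersal groundfish
(3-year bins, weak shift), and a northern piscivore, harvested by two
port-based pelagic fleets and two trawl fleets:

```python
from ecoshift import make_toy_ecosystem, run_all, contrast_tables, realized_F

cfg = make_toy_ecosystem("cps_vs_dts", seed=1)
results = run_all(cfg, seed=1)
print(contrast_tables(results)["biomass_by_group"].round(1))
```

```
                Base  SpatialShift  Warming  mid-SDMs  cool-SDMs  warm-SDMs
phyto            0.0         -16.1    -22.0     -34.3      -27.5      -32.7
zoo              0.0           2.4     -0.0      -0.0        1.3       -9.0
forage_cps       0.0         -58.5     -1.1     -57.7      -57.9      -60.6
groundfish_dts   0.0          -1.0      2.8       1.1        0.6       -1.3
piscivore        0.0          10.8      1.0      11.9       11.8      8.7
```

The columns are percent change vs. Base.  The short-lived pelagic group is
far more responsive to the distribution shift (−58%) than the long-lived
demersal group (−1%), warming alone produces small biomass changes, and the
piscivore gains from the forage fish moving into its range.  The same
mechanism raises the forage stock's realized fishing mortality even though
every fleet's harvest rate is constant:

```python
n, tpy = results["Base"].n_steps, results["Base"].timesteps_per_year
win = slice(n - 6 * tpy, n)
realized_F(results["Base"], "forage_cps", win)      # 2.55e-04 per day
realized_F(results["mid-SDMs"], "forage_cps", win)  # 4.31e-04 per day
```

The stock has drifted into the (larger) northern fleet footprint and the
piscivore's range: fewer old fish, heavier fish, more catch per tonne of
biomass — while in the `minimal` preset, a poleward-shifting stock with a
southern-only fleet shows the opposite: catch falls ~55% while coastwide
biomass rises, decoupling catch trends from stock trends.

A CLI wraps the same calls:

```bash
ecoshift make-fixtures --preset cps_vs_dts --seed 1 --out bundle/
ecoshift run-all --config bundle/config.yaml --seed 1 --out runs/
```

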