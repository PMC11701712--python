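"""Synthetic study inputs: geometry, climatology, warming deltas, SDM
trajectories, food webs and fleets.

Every input the scenario analysis needs can be generated here with the
statistical structure of the real counterparts: a seasonal-cycle baseline
climatology with spatial gradients, cool/mid/warm linear warming ramps,
distribution snapshots that drift poleward over the century, toy food webs
with an availability matrix, and port-based fleets with radius footprints.
Generation is deterministic given the seed; the simulator itself uses no
randomness.

Presets
-------
``minimal``
    4 boxes, producer + zooplankton + one forage fish, one southern fleet.
    The smallest configuration that exercises every mechanism; also the
    canonical demonstration that a poleward-shifting stock decouples catch
    (footprint-bound) from coastwide biomass.
``cps_vs_dts``
    12 boxes and five groups: producer, zooplankton pool, a short-lived
    coastal-pelagic-like forage fish (annual age bins), a long-lived
    demersal groundfish (3-year bins), and a piscivorous predator
    concentrated in the north.  Two port-based pelagic fleets (small
    southern, larger northern) and two demersal trawl fleets.  The forage
    SDM shifts strongly poleward, the groundfish SDM weakly.
``full_scale_structural``
    Structure-only, full-scale counts: 89 boxes, 90 functional groups
    (10 age bins for vertebrates), 51 fleets of which 22 are spatially
    resolved, SDMs for 42 groups.  Placeholder biology; used to exercise
    scale and schema validation, never for dynamical claims.
"""

from __future__ import annotations

import numpy as np

from .config import EcosystemConfig
from .ecology import (AGE_BINS_VERTEBRATE, AvailabilityMatrix,
                      FunctionalGroupDef, GroupState)
from .fisheries import Fleet
from .forcing import ClimatologyYear, EsmDeltaSeries
from .geometry import ModelGeometry, build_synthetic_geometry, cce_like_geometry
from .sdm import DistributionSeries, DistributionSnapshot, ToleranceWindow

__all__ = [
    "PRESETS",
    "make_toy_ecosystem",
    "make_shifting_sdm",
    "make_warming_deltas",
    "make_synthetic_climatology",
]

PRESETS = ("minimal", "cps_vs_dts", "full_scale_structural")

#: End-of-century warming (degC) per delta source; cool < mid < warm spans
#: the range of CMIP5-era downscaled projections for an upwelling system.
DEFAULT_END_WARMING = {"cool": 1.5, "mid": 2.5, "warm": 4.0}


def make_synthetic_climatology(
    geometry: ModelGeometry,
    timesteps_per_year: int,
    mean_south: float = 15.0,
    lat_gradient: float = -0.4,
    amp_nearshore: float = 1.8,
    amp_offshore: float = 1.0,
) -> ClimatologyYear:
    """Per-box sinusoidal seasonal cycle.

    Mean temperature decreases with the latitudinal axis (``lat_gradient``
    degC per degree of latitude northward); the seasonal amplitude is larger
    nearshore (shallow bands) than offshore.
    """
    lat = geometry.latitudinal_axis
    lat0 = lat.min()
    mean = mean_south + lat_gradient * (lat - lat0)
    # amplitude by depth band: shallow = nearshore = larger seasonal swing
    from .geometry import DEPTH_BANDS

    band_index = np.array(
        [DEPTH_BANDS.index(b.depth_band) for b in geometry.boxes], dtype=float
    )
    frac = band_index / max(len(DEPTH_BANDS) - 1, 1)
    amp = amp_nearshore + (amp_offshore - amp_nearshore) * frac
    phase = 2 * np.pi * np.arange(timesteps_per_year) / timesteps_per_year
    temp = mean[None, :] + amp[None, :] * np.sin(phase)[:, None]
    return ClimatologyYear(temperature=temp)


def make_warming_deltas(
    geometry: ModelGeometry,
    end_warming: dict[str, float] | None = None,
    n_years: int = 87,
    start_year: int = 2013,
    lat_modulation: float = 0.0,
) -> dict[str, EsmDeltaSeries]:
    """Three linear warming ramps named cool/mid/warm.

    Deltas ramp linearly from 0 in the first year to the stated end warming
    in the final year.  ``lat_modulation`` optionally tilts the warming
    along the latitudinal axis (fractional range, same for all sources, so
    the cool <= mid <= warm ordering holds per box per year).
    """
    ew = dict(DEFAULT_END_WARMING if end_warming is None else end_warming)
    if not 0 <= ew["cool"] <= ew["mid"] <= ew["warm"]:
        raise ValueError("end warming must satisfy 0 <= cool <= mid <= warm")
    lat = geometry.latitudinal_axis
    span = lat.max() - lat.min()
    if span > 0 and lat_modulation:
        mod = 1.0 + lat_modulation * (lat - lat.mean()) / span
    else:
        mod = np.ones_like(lat)
    ramp = np.arange(n_years) / max(n_years - 1, 1)
    out = {}
    for name, end in ew.items():
        out[name] = EsmDeltaSeries(
            source_name=name,
            start_year=start_year,
            deltas=end * ramp[:, None] * mod[None, :],
        )
    return out


def make_shifting_sdm(
    group_id: str,
    geometry: ModelGeometry,
    start_center: float,
    end_center: float,
    start_year: int,
    end_year: int,
    concentration: float = 1.0,
    cadence: str = "annual",
) -> DistributionSeries:
    """Distribution snapshots from a drifting discretized Gaussian.

    The center moves linearly along the latitudinal axis from
    ``start_center`` to ``end_center``; ``concentration`` is the inverse
    width (per degree of latitude) — larger values concentrate the
    distribution, and in the limit all mass lands in the nearest box.
    Proportions are area-weighted so a uniform density yields the area
    distribution.
    """
    lat = geometry.latitudinal_axis
    area = geometry.areas_km2
    steps = {"annual": 1.0, "monthly": 1 / 12, "seasonal": 0.25}[cadence]
    times = np.arange(start_year, end_year + steps / 2, steps)
    snaps = []
    for t in times:
        frac = 0.0 if end_year == start_year else \
            (t - start_year) / (end_year - start_year)
        center = start_center + frac * (end_center - start_center)
        z = (lat - center) * concentration
        w = area * np.exp(-0.5 * z**2)
        if w.sum() <= 0:  # extreme concentration: all mass to nearest box
            w = np.zeros_like(w)
            w[np.argmin(np.abs(lat - center))] = 1.0
        snaps.append(
            DistributionSnapshot(
                group_id=group_id, time=float(t), proportions=w / w.sum()
            )
        )
    return DistributionSeries(group_id=group_id, snapshots=snaps,
                              cadence=cadence)


def _gaussian_distribution(
    geometry: ModelGeometry, center: float, concentration: float
) -> np.ndarray:
    lat = geometry.latitudinal_axis
    w = geometry.areas_km2 * np.exp(-0.5 * ((lat - center) * concentration) ** 2)
    return w / w.sum()


def _area_distribution(geometry: ModelGeometry) -> np.ndarray:
    a = geometry.areas_km2
    return a / a.sum()


def _fish_def(gid: str, **kw) -> FunctionalGroupDef:
    return FunctionalGroupDef(group_id=gid, kind="age_structured", **kw)


def _equilibrium_numbers(recruits: float, z_per_year: float,
                         years_per_bin: int) -> np.ndarray:
    """Stable-age numbers per bin for a rough annual survival guess."""
    s = np.exp(-z_per_year)
    n = np.zeros(AGE_BINS_VERTEBRATE)
    cohort = recruits
    for a in range(AGE_BINS_VERTEBRATE):
        # bin holds years_per_bin cohorts, each surviving one more year
        bin_total = cohort * (1 - s**years_per_bin) / (1 - s) if s < 1 \
            else cohort * years_per_bin
        n[a] = bin_total
        cohort *= s**years_per_bin
    return n


def make_toy_ecosystem(preset: str, seed: int = 0) -> EcosystemConfig:
    """Build a complete, validated study configuration for a preset."""
    if preset == "minimal":
        return _minimal(seed)
    if preset == "cps_vs_dts":
        return _cps_vs_dts(seed)
    if preset == "full_scale_structural":
        return _full_scale_structural(seed)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# shared biological building blocks
# ---------------------------------------------------------------------------

_FORAGE_W_REF = np.array([5, 12, 20, 27, 33, 38, 42, 45, 47, 48], dtype=float)
_DEMERSAL_W_REF = np.array(
    [20, 80, 180, 320, 480, 650, 820, 980, 1120, 1240], dtype=float
)
_PREDATOR_W_REF = np.array(
    [200, 500, 900, 1300, 1700, 2000, 2300, 2500, 2700, 2800], dtype=float
)


def _producer_def(gid: str, k_per_box: np.ndarray) -> FunctionalGroupDef:
    return FunctionalGroupDef(
        group_id=gid, kind="producer",
        growth_rate=0.8, carrying_capacity=k_per_box,
        linear_mortality=0.005, pool_individual_weight=1e-6,
    )


def _zoo_def(gid: str) -> FunctionalGroupDef:
    return FunctionalGroupDef(
        group_id=gid, kind="pool",
        clearance_rate=1.0e-4, max_ingestion=0.4,
        assimilation_eff=0.3, respiration_coeff=0.004,
        linear_mortality=0.005, quadratic_mortality=2e-6,
        pool_individual_weight=1e-4,
        gape_window=(1e-12, 1.0),
    )


def _forage_def(gid: str) -> FunctionalGroupDef:
    return _fish_def(
        gid,
        years_per_bin=1,
        juvenile_adult_split_bin=2,
        w_ref=_FORAGE_W_REF,
        clearance_rate=1.5e-5, max_ingestion=0.06,
        assimilation_eff=0.3, respiration_coeff=0.005,
        linear_mortality=6e-4,
        gape_window=(1e-9, 0.5),
        recruit_alpha=0.0, recruit_beta=1.0,  # set per preset
    )


def _demersal_def(gid: str) -> FunctionalGroupDef:
    return _fish_def(
        gid,
        years_per_bin=3,
        juvenile_adult_split_bin=2,
        w_ref=_DEMERSAL_W_REF,
        clearance_rate=2.7e-5, max_ingestion=0.02,
        assimilation_eff=0.3, respiration_coeff=2.5e-3,
        linear_mortality=2e-4,
        gape_window=(1e-9, 0.5),
    )


def _predator_def(gid: str) -> FunctionalGroupDef:
    return _fish_def(
        gid,
        years_per_bin=2,
        juvenile_adult_split_bin=2,
        w_ref=_PREDATOR_W_REF,
        clearance_rate=5.6e-5, max_ingestion=0.015,
        assimilation_eff=0.3, respiration_coeff=0.0015,
        linear_mortality=2e-4,
        gape_window=(1e-9, 0.5),
    )


def _age_state(gid: str, geometry, distribution, recruits, z_per_year,
               years_per_bin, w_ref) -> GroupState:
    n_age = _equilibrium_numbers(recruits, z_per_year, years_per_bin)
    return GroupState(
        group_id=gid, kind="age_structured",
        numbers=distribution[:, None] * n_age[None, :],
        weight_at_age=w_ref.copy(),
    )


def _bh_params(gdef: FunctionalGroupDef, state: GroupState,
               annual_deaths: float, steepness_beta_frac: float = 0.25):
    """Set Beverton-Holt alpha/beta so the initial state is a fixed point.

    ``annual_deaths`` approximates the recruits needed to balance mortality;
    beta is placed at ``steepness_beta_frac`` of the initial spawning stock.
    """
    from .ecology import recruit as _recruit

    _, s0 = _recruit(state, gdef)
    gdef.recruit_beta = max(steepness_beta_frac * s0, 1e-9)
    gdef.recruit_alpha = annual_deaths * (gdef.recruit_beta + s0) / max(s0, 1e-9)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _spinup(cfg: EcosystemConfig, years: int) -> EcosystemConfig:
    """Replace initial states with the end of a baseline-scenario run.

    Spinning up under recycled baseline forcing and pinned initial
    distributions puts every preset at quasi-equilibrium before year zero,
    so scenario contrasts are not confounded with initialization transients.
    Deterministic; part of the preset definition.
    """
    from dataclasses import replace as _replace

    from .scenarios import base_spec, run_scenario

    short = _replace(cfg, n_years=years)
    res = run_scenario(base_spec(short), short)
    return _replace(cfg, initial_states=res.final_states)


def _minimal(seed: int) -> EcosystemConfig:
    geom = build_synthetic_geometry(4, 1, seed=seed)
    tpy = 73
    n_years = 30
    start = 2013
    area_p = _area_distribution(geom)
    k_box = 8000.0 * area_p

    defs = {
        "phyto": _producer_def("phyto", k_box),
        "zoo": _zoo_def("zoo"),
        "forage": _forage_def("forage"),
    }
    avail = AvailabilityMatrix()
    avail.set_all_stages("zoo", "phyto", 1.0)
    avail.set_all_stages("forage", "zoo", 1.0)

    lat = geom.latitudinal_axis
    south_center = lat[0]
    north_center = lat[3]
    recruits = 6.0e7
    states = {
        "phyto": GroupState(group_id="phyto", kind="producer",
                            biomass=0.35 * k_box),
        "zoo": GroupState(group_id="zoo", kind="pool",
                          biomass=2500.0 * geom.n_boxes * area_p),
        "forage": _age_state(
            "forage", geom,
            _gaussian_distribution(geom, south_center, 0.6),
            recruits, z_per_year=0.25, years_per_bin=1, w_ref=_FORAGE_W_REF,
        ),
    }
    _bh_params(defs["forage"], states["forage"],
               annual_deaths=recruits)

    # single southern fleet: the stock shifts poleward out of its footprint
    fleets = [
        Fleet(
            fleet_id="cps_south",
            harvest_rates={"forage": 6e-4},
            footprint=frozenset({0, 1}),
        )
    ]
    sdm = {
        "forage": make_shifting_sdm(
            "forage", geom, start_center=south_center,
            end_center=north_center, start_year=start,
            end_year=start + n_years, concentration=0.6,
        )
    }
    clim = make_synthetic_climatology(geom, tpy)
    deltas = make_warming_deltas(geom, n_years=n_years, start_year=start)
    cfg = EcosystemConfig(
        name="minimal",
        geometry=geom, defs=defs, avail=avail, initial_states=states,
        fleets=fleets, sdm_series=sdm, climatology=clim,
        delta_sources=deltas,
        source_roles={"cool": "cool", "mid": "mid", "warm": "warm"},
        start_year=start, n_years=n_years, timesteps_per_year=tpy, seed=seed,
    )
    cfg.validate()
    cfg = _spinup(cfg, years=50)
    cfg.validate()
    return cfg


def _cps_vs_dts(seed: int) -> EcosystemConfig:
    geom = build_synthetic_geometry(6, 2, seed=seed)
    tpy = 73
    n_years = 40
    start = 2013
    area_p = _area_distribution(geom)
    k_box = 24000.0 * area_p
    lat = geom.latitudinal_axis
    row_lat = [lat[r * 2] for r in range(6)]  # nearshore-box latitude per row

    defs = {
        "phyto": _producer_def("phyto", k_box),
        "zoo": _zoo_def("zoo"),
        "forage_cps": _forage_def("forage_cps"),
        "groundfish_dts": _demersal_def("groundfish_dts"),
        "piscivore": _predator_def("piscivore"),
    }
    avail = AvailabilityMatrix()
    avail.set_all_stages("zoo", "phyto", 1.0)
    avail.set_all_stages("forage_cps", "zoo", 1.0)
    avail.set_all_stages("groundfish_dts", "zoo", 0.5)
    avail.set_all_stages("piscivore", "forage_cps", 0.3)
    avail.set_all_stages("piscivore", "zoo", 0.05)
    for ps in ("juv", "adult"):
        avail.set("piscivore", ps, "groundfish_dts", "juv", 0.15)

    forage_start, forage_end = row_lat[1], row_lat[4]
    dts_start, dts_end = row_lat[2], row_lat[3]
    pred_center = row_lat[4]

    r_forage = 1.2e8
    r_dts = 4.0e6
    r_pred = 2.0e4
    states = {
        "phyto": GroupState(group_id="phyto", kind="producer",
                            biomass=0.35 * k_box),
        "zoo": GroupState(group_id="zoo", kind="pool",
                          biomass=2500.0 * geom.n_boxes * area_p),
        "forage_cps": _age_state(
            "forage_cps", geom, _gaussian_distribution(geom, forage_start, 0.5),
            r_forage, z_per_year=0.6, years_per_bin=1, w_ref=_FORAGE_W_REF,
        ),
        "groundfish_dts": _age_state(
            "groundfish_dts", geom, _gaussian_distribution(geom, dts_start, 0.35),
            r_dts, z_per_year=0.18, years_per_bin=3, w_ref=_DEMERSAL_W_REF,
        ),
        "piscivore": _age_state(
            "piscivore", geom, _gaussian_distribution(geom, pred_center, 0.5),
            r_pred, z_per_year=0.25, years_per_bin=2, w_ref=_PREDATOR_W_REF,
        ),
    }
    _bh_params(defs["forage_cps"], states["forage_cps"], annual_deaths=r_forage)
    _bh_params(defs["groundfish_dts"], states["groundfish_dts"],
               annual_deaths=r_dts)
    _bh_params(defs["piscivore"], states["piscivore"], annual_deaths=r_pred)

    # port-based pelagic fleets (port + radius), trawl fleets (box lists);
    # the northern pelagic footprint is larger than the southern one
    centroids = geom.centroids()
    port_south = tuple(centroids[1 * 2])  # nearshore box, row 1
    port_north = tuple(centroids[4 * 2])  # nearshore box, row 4
    fleets = [
        Fleet(fleet_id="cps_south", harvest_rates={"forage_cps": 5e-4},
              port=port_south, radius_km=90.0),
        Fleet(fleet_id="cps_north", harvest_rates={"forage_cps": 5e-4},
              port=port_north, radius_km=220.0),
        Fleet(fleet_id="trawl_south", harvest_rates={"groundfish_dts": 2e-4},
              footprint=frozenset({0, 1, 2, 3, 4, 5})),
        Fleet(fleet_id="trawl_north", harvest_rates={"groundfish_dts": 2e-4},
              footprint=frozenset({6, 7, 8, 9, 10, 11})),
    ]
    sdm = {
        "forage_cps": make_shifting_sdm(
            "forage_cps", geom, start_center=forage_start,
            end_center=forage_end, start_year=start,
            end_year=start + n_years, concentration=0.5,
        ),
        "groundfish_dts": make_shifting_sdm(
            "groundfish_dts", geom, start_center=dts_start,
            end_center=dts_end, start_year=start,
            end_year=start + n_years, concentration=0.35,
        ),
    }
    clim = make_synthetic_climatology(geom, tpy)
    deltas = make_warming_deltas(geom, n_years=n_years, start_year=start)
    cfg = EcosystemConfig(
        name="cps_vs_dts",
        geometry=geom, defs=defs, avail=avail, initial_states=states,
        fleets=fleets, sdm_series=sdm, climatology=clim,
        delta_sources=deltas,
        source_roles={"cool": "cool", "mid": "mid", "warm": "warm"},
        start_year=start, n_years=n_years, timesteps_per_year=tpy, seed=seed,
    )
    cfg.validate()
    cfg = _spinup(cfg, years=80)
    cfg.validate()
    return cfg


def _full_scale_structural(seed: int) -> EcosystemConfig:
    """89 boxes, 90 groups, 51 fleets: structural counts only."""
    rng = np.random.default_rng(seed)
    geom = cce_like_geometry(seed=seed)
    tpy = 730  # 12-h steps
    n_years = 87
    start = 2013
    area_p = _area_distribution(geom)
    lat = geom.latitudinal_axis

    defs: dict[str, FunctionalGroupDef] = {}
    states: dict[str, GroupState] = {}
    avail = AvailabilityMatrix()

    producers = ["phyto_small", "phyto_large"]
    for gid in producers:
        k = 50000.0 * area_p
        defs[gid] = _producer_def(gid, k)
        states[gid] = GroupState(group_id=gid, kind="producer", biomass=0.7 * k)

    pools = [f"pool_{i:02d}" for i in range(18)]
    for gid in pools:
        defs[gid] = _zoo_def(gid)
        states[gid] = GroupState(group_id=gid, kind="pool",
                                 biomass=5000.0 * area_p)
        avail.set_all_stages(gid, producers[0], 0.8)
        avail.set_all_stages(gid, producers[1], 0.5)

    fishes = [f"fish_{i:02d}" for i in range(70)]
    for i, gid in enumerate(fishes):
        w_ref = _FORAGE_W_REF * float(rng.uniform(0.5, 40.0))
        defs[gid] = _fish_def(
            gid,
            years_per_bin=int(rng.integers(1, 4)),
            juvenile_adult_split_bin=2,
            w_ref=w_ref,
            clearance_rate=1.5e-4, max_ingestion=0.04,
            assimilation_eff=0.3, respiration_coeff=2e-3,
            linear_mortality=3e-4,
            gape_window=(1e-9, 0.5),
            recruit_alpha=1e7, recruit_beta=1e3,
        )
        center = float(rng.uniform(lat.min(), lat.max()))
        states[gid] = _age_state(
            gid, geom, _gaussian_distribution(geom, center, 0.3),
            recruits=1e7, z_per_year=0.5,
            years_per_bin=int(defs[gid].years_per_bin[0]), w_ref=w_ref,
        )
        avail.set_all_stages(gid, pools[i % len(pools)], 0.8)

    # SDMs for 42 of the 90 groups, drifting poleward
    sdm = {}
    for gid in fishes[:42]:
        c0 = float(rng.uniform(lat.min(), lat.min() + 0.6 * np.ptp(lat)))
        sdm[gid] = make_shifting_sdm(
            gid, geom, start_center=c0,
            end_center=c0 + 0.25 * np.ptp(lat),
            start_year=start, end_year=start + n_years, concentration=0.3,
        )

    # 22 spatially resolved port fleets + 29 generic whole-domain fleets
    centroids = geom.centroids()
    nearshore = [b.id for b in geom.boxes if b.depth_band == "50"]
    fleets = []
    for i in range(22):
        box = nearshore[int(rng.integers(0, len(nearshore)))]
        fleets.append(
            Fleet(
                fleet_id=f"port_fleet_{i:02d}",
                harvest_rates={fishes[i % 70]: 2e-4},
                port=tuple(centroids[box]),
                radius_km=float(rng.uniform(100, 300)),
            )
        )
    for i in range(29):
        fleets.append(
            Fleet(
                fleet_id=f"generic_fleet_{i:02d}",
                harvest_rates={fishes[(22 + i) % 70]: 1e-4},
                spatially_resolved=False,
            )
        )

    clim = make_synthetic_climatology(geom, tpy)
    deltas = make_warming_deltas(geom, n_years=n_years, start_year=start)
    cfg = EcosystemConfig(
        name="full_scale_structural",
        geometry=geom, defs=defs, avail=avail, initial_states=states,
        fleets=fleets, sdm_series=sdm, climatology=clim,
        delta_sources=deltas,
        source_roles={"cool": "cool", "mid": "mid", "warm": "warm"},
        start_year=start, n_years=n_years, timesteps_per_year=tpy, seed=seed,
    )
    cfg.validate()
    return cfg
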