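"""Shared fixtures: toy configs and the scenario runs several tests reuse.

Scenario runs are session-scoped because they are the expensive part of the
suite; every test that needs the Base / combined / warming trajectories
shares the same deterministic run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ecoshift import (EcosystemConfig, Fleet, FunctionalGroupDef, GroupState,
                      build_scenarios, build_synthetic_geometry,
                      make_toy_ecosystem, make_warming_deltas, run_scenario)
from ecoshift.ecology import AvailabilityMatrix
from ecoshift.forcing import ClimatologyYear
from ecoshift.scenarios import ScenarioSpec


@pytest.fixture(scope="session")
def minimal_cfg() -> EcosystemConfig:
    return make_toy_ecosystem("minimal", seed=1)


@pytest.fixture(scope="session")
def cps_cfg() -> EcosystemConfig:
    return make_toy_ecosystem("cps_vs_dts", seed=1)


@pytest.fixture(scope="session")
def cps_specs(cps_cfg):
    return {s.name: s for s in build_scenarios(cps_cfg)}


@pytest.fixture(scope="session")
def base_cps(cps_cfg, cps_specs):
    return run_scenario(cps_specs["Base"], cps_cfg)


@pytest.fixture(scope="session")
def combined_cps(cps_cfg, cps_specs):
    """Projected mid warming + time-varying SDMs."""
    return run_scenario(cps_specs["mid-SDMs"], cps_cfg)


@pytest.fixture(scope="session")
def shift_cps(cps_cfg, cps_specs):
    return run_scenario(cps_specs["SpatialShift"], cps_cfg)


@pytest.fixture(scope="session")
def warming_static_runs(cps_cfg):
    """Static-SDM runs under the cool / mid / warm projections."""
    return {
        role: run_scenario(
            ScenarioSpec(f"W-{role}", f"projected:{role}",
                         "static_initial_year"),
            cps_cfg,
        )
        for role in ("cool", "mid", "warm")
    }


@pytest.fixture(scope="session")
def pinned_shift_cps(cps_cfg):
    """Time-varying SDM mode but every series frozen to its first snapshot."""
    cfg = replace(
        cps_cfg,
        sdm_series={g: s.pinned_to_first()
                    for g, s in cps_cfg.sdm_series.items()},
    )
    return run_scenario(
        ScenarioSpec("SS-pinned", "baseline", "time_varying"), cfg
    )


@pytest.fixture(scope="session")
def base_min(minimal_cfg):
    spec = {s.name: s for s in build_scenarios(minimal_cfg)}["Base"]
    return run_scenario(spec, minimal_cfg)


@pytest.fixture(scope="session")
def shift_min(minimal_cfg):
    spec = {s.name: s for s in build_scenarios(minimal_cfg)}["SpatialShift"]
    return run_scenario(spec, minimal_cfg)


def single_stock_config(f_rate: float, m_rate: float,
                        n_years: int = 10) -> EcosystemConfig:
    """One box, one unfed stock, constant fishing + linear mortality.

    The no-predation, no-recruitment limit whose numbers follow the exact
    exponential decline N0 exp(-(F+m) t).
    """
    geom = build_synthetic_geometry(1, 1, seed=0)
    tpy = 73
    w_ref = np.linspace(10, 100, 10)
    gdef = FunctionalGroupDef(
        group_id="stock", kind="age_structured", years_per_bin=1,
        w_ref=w_ref, clearance_rate=0.0, max_ingestion=0.0,
        respiration_coeff=0.0, linear_mortality=m_rate,
        recruit_alpha=0.0, q10_sensitive=False,
    )
    numbers = np.full((1, 10), 1.0e6)
    state = GroupState(group_id="stock", kind="age_structured",
                       numbers=numbers, weight_at_age=w_ref.copy())
    clim = ClimatologyYear(temperature=np.full((tpy, 1), 15.0))
    fleets = [Fleet(fleet_id="f", harvest_rates={"stock": f_rate},
                    spatially_resolved=False)]
    cfg = EcosystemConfig(
        name="single-stock",
        geometry=geom,
        defs={"stock": gdef},
        avail=AvailabilityMatrix(),
        initial_states={"stock": state},
        fleets=fleets,
        sdm_series={},
        climatology=clim,
        delta_sources=make_warming_deltas(geom, n_years=n_years),
        source_roles={"cool": "cool", "mid": "mid", "warm": "warm"},
        start_year=2013, n_years=n_years, timesteps_per_year=tpy,
    )
    cfg.validate()
    return cfg


def eoc(result, series):
    """End-of-century mean helper aligned on step boundaries."""
    from ecoshift.metrics import end_of_century_mean

    return end_of_century_mean(series, result.time)


def eoc_flux(result, series):
    from ecoshift.metrics import end_of_century_mean

    return end_of_century_mean(series, result.time[1:])
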