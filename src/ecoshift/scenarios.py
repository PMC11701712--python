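"""The six-scenario climate factorial and the scenario runner.

The factorial crosses two drivers: oceanography (recycled baseline year vs.
a projected warming time series from a named delta source) and species
distributions (pinned to the initial snapshot vs. time-varying SDM forcing):

1. Base               — baseline ocean, static distributions
2. SpatialShift       — baseline ocean, time-varying SDMs
3. Warming            — projected mid ocean, static distributions
4. <mid>-SDMs         — projected mid ocean, time-varying SDMs
5. <cool>-SDMs        — projected cool ocean, time-varying SDMs
6. <warm>-SDMs        — projected warm ocean, time-varying SDMs

A run is fully deterministic given (spec, config, seed); the seed only
enters provenance (randomness lives in synthetic input generation, never in
the dynamics).
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import EcosystemConfig
from .ecology import Ecosystem, MortalityLedger, step_ecosystem
from .fisheries import build_fishing_field
from .forcing import ForcingSeries, delta_downscale, recycle_baseline

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioError",
    "SimulationBlowUp",
    "base_spec",
    "build_scenarios",
    "run_scenario",
    "run_all",
]

BASE_NAME = "Base"
SPATIAL_SHIFT_NAME = "SpatialShift"
WARMING_NAME = "Warming"

SDM_STATIC = "static_initial_year"
SDM_TIME_VARYING = "time_varying"


class ScenarioError(ValueError):
    pass


class SimulationBlowUp(RuntimeError):
    """Non-finite state encountered; carries a diagnostic snapshot."""

    def __init__(self, message: str, snapshot: dict):
        super().__init__(message)
        self.snapshot = snapshot


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial."""

    name: str
    oceanography: str  # "baseline" or "projected:<source_name>"
    sdm_mode: str  # SDM_STATIC or SDM_TIME_VARYING

    def __post_init__(self):
        if self.sdm_mode not in (SDM_STATIC, SDM_TIME_VARYING):
            raise ScenarioError(f"unknown sdm_mode {self.sdm_mode!r}")
        if self.oceanography != "baseline" and not \
                self.oceanography.startswith("projected:"):
            raise ScenarioError(
                f"oceanography must be 'baseline' or 'projected:<source>', "
                f"got {self.oceanography!r}"
            )

    @property
    def delta_source(self) -> str | None:
        if self.oceanography.startswith("projected:"):
            return self.oceanography.split(":", 1)[1]
        return None


def base_spec(config: EcosystemConfig) -> ScenarioSpec:
    return ScenarioSpec(BASE_NAME, "baseline", SDM_STATIC)


def build_scenarios(config: EcosystemConfig) -> list[ScenarioSpec]:
    """The six-spec factorial from a config with cool/mid/warm delta sources."""
    roles = config.source_roles
    for role in ("cool", "mid", "warm"):
        if role not in roles:
            raise ScenarioError(f"config lacks a designated {role!r} source")
    cool, mid, warm = roles["cool"], roles["mid"], roles["warm"]
    return [
        ScenarioSpec(BASE_NAME, "baseline", SDM_STATIC),
        ScenarioSpec(SPATIAL_SHIFT_NAME, "baseline", SDM_TIME_VARYING),
        ScenarioSpec(WARMING_NAME, f"projected:{mid}", SDM_STATIC),
        ScenarioSpec(f"{mid}-SDMs", f"projected:{mid}", SDM_TIME_VARYING),
        ScenarioSpec(f"{cool}-SDMs", f"projected:{cool}", SDM_TIME_VARYING),
        ScenarioSpec(f"{warm}-SDMs", f"projected:{warm}", SDM_TIME_VARYING),
    ]


@dataclass
class ScenarioResult:
    """Full trajectory of one scenario run.

    State arrays are sampled at step boundaries (length ``n_steps + 1``);
    flux arrays (ledgers, catch) are per step (length ``n_steps``).
    """

    spec: ScenarioSpec
    time: np.ndarray  # decimal years at step boundaries
    dt_days: float
    timesteps_per_year: int
    start_year: int
    group_kinds: dict[str, str]
    biomass_box: dict[str, np.ndarray]  # gid -> (n_steps+1, n_boxes)
    numbers: dict[str, np.ndarray]  # age-structured gid -> (n_steps+1, n_ages)
    weight: dict[str, np.ndarray]  # age-structured gid -> (n_steps+1, n_ages)
    ledgers: dict[str, MortalityLedger]
    catch: dict[str, np.ndarray]  # gid -> (n_steps, n_fleets)
    fleet_ids: list[str]
    provenance: dict
    final_states: dict = field(default_factory=dict)  # gid -> GroupState

    # -- accessors -----------------------------------------------------------
    @property
    def n_steps(self) -> int:
        return len(self.time) - 1

    def biomass_total(self, group_id: str) -> np.ndarray:
        return self.biomass_box[group_id].sum(axis=1)

    def catch_total(self, group_id: str) -> np.ndarray:
        return self.catch[group_id].sum(axis=1)

    def catch_by_fleet(self, fleet_id: str, group_id: str) -> np.ndarray:
        return self.catch[group_id][:, self.fleet_ids.index(fleet_id)]

    def annual_catch(self, group_id: str, final_years: int = 5) -> float:
        """Mean annual catch (tonnes/year) over the final simulated years."""
        tpy = self.timesteps_per_year
        per_year = self.catch_total(group_id).reshape(-1, tpy).sum(axis=1)
        k = min(final_years, len(per_year))
        return float(per_year[-k:].mean())

    def final_window(self, years: int = 6) -> slice:
        """Step-boundary slice covering the final ``years`` simulated years."""
        return slice(len(self.time) - years * self.timesteps_per_year - 1,
                     len(self.time))

    def catch_records(self) -> pd.DataFrame:
        """Annual catch by fleet and group, long format."""
        tpy = self.timesteps_per_year
        rows = []
        for gid, arr in self.catch.items():
            annual = arr.reshape(-1, tpy, arr.shape[1]).sum(axis=1)
            for yi in range(annual.shape[0]):
                for fi, fid in enumerate(self.fleet_ids):
                    if annual[yi, fi] > 0:
                        rows.append((fid, gid, self.start_year + yi,
                                     annual[yi, fi]))
        return pd.DataFrame(
            rows, columns=["fleet_id", "group_id", "year", "catch"]
        )


def _forcing_for(spec: ScenarioSpec, config: EcosystemConfig) -> ForcingSeries:
    if spec.oceanography == "baseline":
        return recycle_baseline(config.climatology, config.n_years,
                                start_year=config.start_year)
    src = spec.delta_source
    if src not in config.delta_sources:
        raise ScenarioError(f"unknown delta source {src!r}")
    years = range(config.start_year, config.start_year + config.n_years)
    return delta_downscale(config.climatology, config.delta_sources[src], years)


def run_scenario(
    spec: ScenarioSpec, config: EcosystemConfig, seed: int = 0
) -> ScenarioResult:
    """Run one scenario to completion; deterministic given (spec, config, seed)."""
    config.validate()
    forcing = _forcing_for(spec, config)
    tpy = config.timesteps_per_year
    n_steps = config.n_years * tpy
    dt = config.dt_days

    # SDM mode: static pins every forced group to its first snapshot
    if spec.sdm_mode == SDM_STATIC:
        sdm_active = {gid: s.pinned_to_first()
                      for gid, s in config.sdm_series.items()}
    else:
        sdm_active = dict(config.sdm_series)
    pinned = {
        gid: st.distribution()
        for gid, st in config.initial_states.items()
        if gid not in sdm_active
    }

    fishing = build_fishing_field(config.fleets, config.group_ids,
                                  config.geometry)
    eco = Ecosystem(
        geometry=config.geometry,
        defs=config.defs,
        avail=config.avail,
        states={gid: st.copy() for gid, st in config.initial_states.items()},
        fishing=fishing,
        sdm_series=sdm_active,
        pinned_distributions=pinned,
    )
    eco.validate()

    nb = config.geometry.n_boxes
    n_fleets = len(config.fleets)
    biomass_box, numbers, weight, ledgers, catch = {}, {}, {}, {}, {}
    for gid, gdef in config.defs.items():
        biomass_box[gid] = np.zeros((n_steps + 1, nb))
        ncomp = gdef.n_age_bins if gdef.kind == "age_structured" else 1
        ledgers[gid] = MortalityLedger(n_steps, ncomp)
        catch[gid] = np.zeros((n_steps, n_fleets))
        if gdef.kind == "age_structured":
            numbers[gid] = np.zeros((n_steps + 1, gdef.n_age_bins))
            weight[gid] = np.zeros((n_steps + 1, gdef.n_age_bins))

    def record(i: int):
        for gid, st in eco.states.items():
            biomass_box[gid][i] = st.biomass_by_box()
            if st.kind == "age_structured":
                numbers[gid][i] = st.numbers_at_age()
                weight[gid][i] = st.weight_at_age

    record(0)
    for i in range(n_steps):
        t = config.start_year + i / tpy
        step_ecosystem(
            eco,
            temp_field=forcing.at_step(i),
            t=t,
            dt=dt,
            annual=((i + 1) % tpy == 0),
            ledgers=ledgers,
            catch_by_fleet=catch,
            step_index=i,
        )
        record(i + 1)
        for gid, st in eco.states.items():
            arr = st.numbers if st.kind == "age_structured" else st.biomass
            if not np.all(np.isfinite(arr)):
                raise SimulationBlowUp(
                    f"non-finite state in group {gid} at step {i} "
                    f"(t={t:.3f})",
                    snapshot={
                        "step": i, "t": t, "group": gid,
                        "biomass_totals": {
                            g: float(s.biomass_by_box().sum())
                            for g, s in eco.states.items()
                        },
                    },
                )

    time = config.start_year + np.arange(n_steps + 1) / tpy
    return ScenarioResult(
        spec=spec,
        time=time,
        dt_days=dt,
        timesteps_per_year=tpy,
        start_year=config.start_year,
        group_kinds={gid: d.kind for gid, d in config.defs.items()},
        biomass_box=biomass_box,
        numbers=numbers,
        weight=weight,
        ledgers=ledgers,
        catch=catch,
        fleet_ids=[f.fleet_id for f in config.fleets],
        final_states={gid: st.copy() for gid, st in eco.states.items()},
        provenance={
            "scenario": spec.name,
            "oceanography": spec.oceanography,
            "sdm_mode": spec.sdm_mode,
            "config_hash": config.config_hash(),
            "config_name": config.name,
            "seed": seed,
            "code_version": _pkg_version,
        },
    )


@dataclass
class ScenarioFailure:
    """Error record for one failed scenario in a batch run."""

    spec: ScenarioSpec
    error: str
    traceback: str


def run_all(config: EcosystemConfig, seed: int = 0) -> dict:
    """Run the six-scenario factorial; failures are isolated per scenario."""
    out: dict[str, ScenarioResult | ScenarioFailure] = {}
    for spec in build_scenarios(config):
        try:
            out[spec.name] = run_scenario(spec, config, seed=seed)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            out[spec.name] = ScenarioFailure(
                spec=spec, error=str(exc), traceback=traceback.format_exc()
            )
    return out
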