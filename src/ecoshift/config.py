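"""Ecosystem configuration: everything a scenario run needs, serializable.

An :class:`EcosystemConfig` bundles the geometry, group definitions,
availability matrix, initial states, fleets, SDM forcing series, baseline
climatology and the named warming-delta sources.  It round-trips through a
plain-dict form (and YAML) so that complete study setups can be written to
disk as structured text and re-run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .ecology import AvailabilityMatrix, FunctionalGroupDef, GroupState
from .forcing import ClimatologyYear, EsmDeltaSeries
from .geometry import ModelGeometry, geometry_from_geojson, geometry_to_geojson
from .fisheries import Fleet
from .sdm import DistributionSeries, DistributionSnapshot, ToleranceWindow

__all__ = ["EcosystemConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class EcosystemConfig:
    """A complete, runnable study configuration."""

    name: str
    geometry: ModelGeometry
    defs: dict[str, FunctionalGroupDef]
    avail: AvailabilityMatrix
    initial_states: dict[str, GroupState]
    fleets: list[Fleet]
    sdm_series: dict[str, DistributionSeries]
    climatology: ClimatologyYear
    delta_sources: dict[str, EsmDeltaSeries]
    source_roles: dict[str, str]  # {"cool": name, "mid": name, "warm": name}
    start_year: int = 2013
    n_years: int = 30
    timesteps_per_year: int = 73
    seed: int = 0

    @property
    def dt_days(self) -> float:
        return 365.0 / self.timesteps_per_year

    @property
    def group_ids(self) -> list[str]:
        return list(self.defs)

    def validate(self) -> None:
        self.geometry.validate()
        nb = self.geometry.n_boxes
        if self.climatology.n_boxes != nb:
            raise ConfigError("climatology does not cover the geometry")
        if self.climatology.timesteps_per_year != self.timesteps_per_year:
            raise ConfigError("climatology resolution != timesteps_per_year")
        for gid, st in self.initial_states.items():
            if gid not in self.defs:
                raise ConfigError(f"initial state for unknown group {gid}")
        for gid in self.defs:
            if gid not in self.initial_states:
                raise ConfigError(f"missing initial state for group {gid}")
        for gid, series in self.sdm_series.items():
            if gid not in self.defs:
                raise ConfigError(f"SDM series for unknown group {gid}")
            for snap in series.snapshots:
                if snap.proportions.shape[0] != nb:
                    raise ConfigError(f"SDM snapshot for {gid} wrong box count")
        for role in ("cool", "mid", "warm"):
            if role not in self.source_roles:
                raise ConfigError(f"missing delta source role {role!r}")
            if self.source_roles[role] not in self.delta_sources:
                raise ConfigError(f"role {role!r} names unknown delta source")
        for f in self.fleets:
            for gid in f.portfolio:
                if gid not in self.defs:
                    raise ConfigError(
                        f"fleet {f.fleet_id} targets unknown group {gid}"
                    )

    def with_fleets(self, fleets: list[Fleet]) -> "EcosystemConfig":
        return replace(self, fleets=fleets)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        defs = {}
        for gid, d in self.defs.items():
            defs[gid] = {
                "kind": d.kind,
                "clearance_rate": d.clearance_rate,
                "max_ingestion": d.max_ingestion,
                "assimilation_eff": d.assimilation_eff,
                "respiration_coeff": d.respiration_coeff,
                "linear_mortality": d.linear_mortality,
                "quadratic_mortality": d.quadratic_mortality,
                "gape_window": list(d.gape_window),
                "recruit_alpha": d.recruit_alpha,
                "recruit_beta": d.recruit_beta,
                "tolerance": [d.tolerance.t_min, d.tolerance.t_max],
                "q10_sensitive": d.q10_sensitive,
                "pool_individual_weight": d.pool_individual_weight,
                "growth_rate": d.growth_rate,
                "carrying_capacity": arr(d.carrying_capacity),
                "starvation_floor": d.starvation_floor,
            }
            if d.kind == "age_structured":
                defs[gid].update(
                    n_age_bins=d.n_age_bins,
                    years_per_bin=arr(d.years_per_bin),
                    maturity_at_bin=arr(d.maturity_at_bin),
                    juvenile_adult_split_bin=d.juvenile_adult_split_bin,
                    w_ref=arr(d.w_ref),
                )
        states = {}
        for gid, st in self.initial_states.items():
            if st.kind == "age_structured":
                states[gid] = {
                    "kind": st.kind,
                    "numbers": arr(st.numbers),
                    "weight_at_age": arr(st.weight_at_age),
                }
            else:
                states[gid] = {"kind": st.kind, "biomass": arr(st.biomass)}
        fleets = [
            {
                "fleet_id": f.fleet_id,
                "harvest_rates": dict(f.harvest_rates),
                "footprint": sorted(f.footprint) if f.footprint else None,
                "port": list(f.port) if f.port else None,
                "radius_km": f.radius_km,
                "spatially_resolved": f.spatially_resolved,
            }
            for f in self.fleets
        ]
        sdm = {
            gid: {
                "cadence": s.cadence,
                "snapshots": [
                    {"time": snap.time, "proportions": arr(snap.proportions)}
                    for snap in s.snapshots
                ],
            }
            for gid, s in self.sdm_series.items()
        }
        return {
            "name": self.name,
            "geometry": geometry_to_geojson(self.geometry),
            "defs": defs,
            "availability": [list(k) + [v] for k, v in self.avail.items()],
            "initial_states": states,
            "fleets": fleets,
            "sdm_series": sdm,
            "climatology": {"temperature": arr(self.climatology.temperature)},
            "delta_sources": {
                name: {"start_year": d.start_year, "deltas": arr(d.deltas)}
                for name, d in self.delta_sources.items()
            },
            "source_roles": dict(self.source_roles),
            "start_year": self.start_year,
            "n_years": self.n_years,
            "timesteps_per_year": self.timesteps_per_year,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EcosystemConfig":
        geometry = geometry_from_geojson(doc["geometry"])
        defs = {}
        for gid, d in doc["defs"].items():
            kwargs = dict(
                group_id=gid,
                kind=d["kind"],
                clearance_rate=d["clearance_rate"],
                max_ingestion=d["max_ingestion"],
                assimilation_eff=d["assimilation_eff"],
                respiration_coeff=d["respiration_coeff"],
                linear_mortality=d["linear_mortality"],
                quadratic_mortality=d.get("quadratic_mortality", 0.0),
                gape_window=tuple(d["gape_window"]),
                recruit_alpha=d["recruit_alpha"],
                recruit_beta=d["recruit_beta"],
                tolerance=ToleranceWindow(*d["tolerance"]),
                q10_sensitive=d["q10_sensitive"],
                pool_individual_weight=d["pool_individual_weight"],
                growth_rate=d["growth_rate"],
                carrying_capacity=np.asarray(d["carrying_capacity"]),
                starvation_floor=d["starvation_floor"],
            )
            if d["kind"] == "age_structured":
                kwargs.update(
                    n_age_bins=d["n_age_bins"],
                    years_per_bin=np.asarray(d["years_per_bin"]),
                    maturity_at_bin=np.asarray(d["maturity_at_bin"]),
                    juvenile_adult_split_bin=d["juvenile_adult_split_bin"],
                    w_ref=np.asarray(d["w_ref"]),
                )
            defs[gid] = FunctionalGroupDef(**kwargs)
        avail = AvailabilityMatrix(
            {tuple(row[:4]): row[4] for row in doc["availability"]}
        )
        states = {}
        for gid, s in doc["initial_states"].items():
            if s["kind"] == "age_structured":
                states[gid] = GroupState(
                    group_id=gid, kind=s["kind"],
                    numbers=np.asarray(s["numbers"]),
                    weight_at_age=np.asarray(s["weight_at_age"]),
                )
            else:
                states[gid] = GroupState(
                    group_id=gid, kind=s["kind"],
                    biomass=np.asarray(s["biomass"]),
                )
        fleets = [
            Fleet(
                fleet_id=f["fleet_id"],
                harvest_rates=dict(f["harvest_rates"]),
                footprint=frozenset(f["footprint"]) if f["footprint"] else None,
                port=tuple(f["port"]) if f["port"] else None,
                radius_km=f["radius_km"],
                spatially_resolved=f["spatially_resolved"],
            )
            for f in doc["fleets"]
        ]
        sdm = {
            gid: DistributionSeries(
                group_id=gid,
                cadence=s["cadence"],
                snapshots=[
                    DistributionSnapshot(
                        group_id=gid, time=snap["time"],
                        proportions=np.asarray(snap["proportions"]),
                    )
                    for snap in s["snapshots"]
                ],
            )
            for gid, s in doc["sdm_series"].items()
        }
        cfg = cls(
            name=doc["name"],
            geometry=geometry,
            defs=defs,
            avail=avail,
            initial_states=states,
            fleets=fleets,
            sdm_series=sdm,
            climatology=ClimatologyYear(
                temperature=np.asarray(doc["climatology"]["temperature"])
            ),
            delta_sources={
                name: EsmDeltaSeries(
                    source_name=name, start_year=d["start_year"],
                    deltas=np.asarray(d["deltas"]),
                )
                for name, d in doc["delta_sources"].items()
            },
            source_roles=dict(doc["source_roles"]),
            start_year=doc["start_year"],
            n_years=doc["n_years"],
            timesteps_per_year=doc["timesteps_per_year"],
            seed=doc.get("seed", 0),
        )
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        # round through JSON to coerce numpy scalars to plain Python numbers
        doc = json.loads(json.dumps(self.to_dict()))
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, default_flow_style=True, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EcosystemConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
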