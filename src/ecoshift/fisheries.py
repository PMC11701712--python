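"""Spatially footprinted fishing fleets with static harvest rates.

Each fleet applies a fixed per-day harvest rate to the groups in its
portfolio, but only inside its spatial footprint — either an explicit set of
box ids or a disc of given radius around a port location.  Because rates
are static while distributions shift, the *realized* coastwide fishing
mortality of a stock emerges from its spatial overlap with fished boxes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.ops import transform

from .ecology import FishingField
from .geometry import KM_PER_DEG_LAT, ModelGeometry

__all__ = [
    "Fleet",
    "CatchRecord",
    "FisheriesError",
    "EmptyFootprintWarning",
    "footprint_from_port",
    "fleet_fishing_rate",
    "build_fishing_field",
    "realized_F",
    "calibrate_harvest_rates",
    "CalibrationResult",
    "read_fleets_csv",
    "write_fleets_csv",
]


class FisheriesError(ValueError):
    pass


class EmptyFootprintWarning(UserWarning):
    """A port-radius footprint intersects no boxes."""


@dataclass
class Fleet:
    """One fishing fleet.

    ``harvest_rates`` maps target group id -> per-day rate applied inside
    the footprint.  Spatially resolved fleets carry either an explicit
    ``footprint`` (set of box ids) or a ``port`` (lon, lat) and ``radius_km``
    from which the footprint is derived; non-spatial fleets cover the whole
    domain.
    """

    fleet_id: str
    harvest_rates: dict[str, float]
    footprint: frozenset[int] | None = None
    port: tuple[float, float] | None = None
    radius_km: float | None = None
    spatially_resolved: bool = True

    def __post_init__(self):
        for gid, rate in self.harvest_rates.items():
            if rate < 0:
                raise FisheriesError(f"{self.fleet_id}: negative rate for {gid}")
        if self.spatially_resolved and self.footprint is None and self.port is None:
            raise FisheriesError(
                f"{self.fleet_id}: spatially resolved fleet needs a footprint "
                "or a port + radius"
            )

    @property
    def portfolio(self) -> set[str]:
        return set(self.harvest_rates)

    def resolve_footprint(self, geom: ModelGeometry) -> frozenset[int]:
        """Box ids this fleet can fish in."""
        if not self.spatially_resolved:
            return frozenset(range(geom.n_boxes))
        if self.footprint is not None:
            return self.footprint
        return footprint_from_port(self.port, self.radius_km, geom)


@dataclass(frozen=True)
class CatchRecord:
    fleet_id: str
    group_id: str
    year: int
    catch: float  # tonnes

    def __post_init__(self):
        if self.catch < 0:
            raise FisheriesError("catch must be non-negative")


def footprint_from_port(
    port: tuple[float, float], radius_km: float, geom: ModelGeometry
) -> frozenset[int]:
    """Boxes whose polygon intersects the disc of ``radius_km`` around the port.

    The disc is evaluated in a local flat-earth projection centred on the
    port (km east/north), adequate at footprint scales.  An empty result
    emits :class:`EmptyFootprintWarning`.
    """
    if radius_km <= 0:
        raise FisheriesError("radius must be positive")
    lon0, lat0 = port
    coslat = math.cos(math.radians(lat0))

    def to_km(x, y):
        return ((np.asarray(x) - lon0) * KM_PER_DEG_LAT * coslat,
                (np.asarray(y) - lat0) * KM_PER_DEG_LAT)

    disc = Point(0.0, 0.0).buffer(radius_km, quad_segs=64)
    hits = set()
    for b in geom.boxes:
        poly_km = transform(to_km, b.shapely())
        if poly_km.intersects(disc):
            hits.add(b.id)
    if not hits:
        warnings.warn(
            f"port {port} radius {radius_km} km intersects no boxes",
            EmptyFootprintWarning, stacklevel=2,
        )
    return frozenset(hits)


def fleet_fishing_rate(
    fleets: list[Fleet], group_id: str, box_id: int, geom: ModelGeometry
) -> float:
    """Summed per-day rate on ``group_id`` in ``box_id`` across all fleets."""
    total = 0.0
    for f in fleets:
        rate = f.harvest_rates.get(group_id, 0.0)
        if rate > 0 and box_id in f.resolve_footprint(geom):
            total += rate
    return total


def build_fishing_field(
    fleets: list[Fleet], group_ids, geom: ModelGeometry
) -> FishingField:
    """Precompute per-box rates and per-fleet allocation shares.

    Overlapping fleets are additive; each fleet's share of a box's catch is
    its share of the summed rate there (exact shared bookkeeping with the
    mortality ledger).
    """
    nb = geom.n_boxes
    fleet_ids = [f.fleet_id for f in fleets]
    if len(set(fleet_ids)) != len(fleet_ids):
        raise FisheriesError("duplicate fleet ids")
    footprints = [f.resolve_footprint(geom) for f in fleets]
    rates: dict[str, np.ndarray] = {}
    shares: dict[str, np.ndarray] = {}
    for gid in group_ids:
        per_fleet = np.zeros((len(fleets), nb))
        for i, (f, fp) in enumerate(zip(fleets, footprints)):
            r = f.harvest_rates.get(gid, 0.0)
            if r > 0:
                per_fleet[i, list(fp)] = r
        total = per_fleet.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sh = np.where(total > 0, per_fleet / np.maximum(total, 1e-300), 0.0)
        rates[gid] = total
        shares[gid] = sh
    return FishingField(rates=rates, shares=shares, fleet_ids=fleet_ids)


def realized_F(result, group_id: str, window: slice | None = None) -> float:
    """Catch-weighted coastwide fishing mortality rate (per day).

    Total catch of the group over the timestep window divided by (mean
    coastwide biomass x window length in days), computed from a
    ScenarioResult.  Returns NaN where biomass is zero.
    """
    catch = result.catch_total(group_id)  # (n_steps,)
    biom = result.biomass_total(group_id)  # (n_steps,)
    if window is None:
        window = slice(0, len(catch))
    c = catch[window].sum()
    b = biom[window].mean()
    days = len(catch[window]) * result.dt_days
    if days == 0:
        raise FisheriesError("empty window")
    if b <= 0:
        return float("nan")
    return float(c / (b * days))


@dataclass
class CalibrationResult:
    """Outcome of iterative harvest-rate calibration."""

    fleets: list[Fleet]
    achieved_catch: dict[str, float]  # tonnes/year at quasi-equilibrium
    residuals: dict[str, float]  # relative error vs target
    converged: bool
    n_iter: int


def calibrate_harvest_rates(
    target_catch: dict[str, float],
    config,
    tol: float = 0.05,
    max_iter: int = 8,
    run_scenario_fn=None,
) -> CalibrationResult:
    """Scale fleet rates until base-scenario annual catch matches targets.

    Each iteration runs the base scenario, measures annual catch per group
    averaged over the final years, and multiplies every fleet's rate on that
    group by ``target / achieved`` — preserving the relative allocation
    among fleets that share a target.  Non-convergence is reported in the
    result, not raised.
    """
    from .scenarios import run_scenario, base_spec  # local import avoids cycle

    run = run_scenario_fn or (lambda cfg: run_scenario(base_spec(cfg), cfg))
    cfg = config
    for gid, tgt in target_catch.items():
        if tgt <= 0:
            raise FisheriesError(f"target catch for {gid} must be positive")
        if not any(gid in f.portfolio for f in cfg.fleets):
            raise FisheriesError(f"no fleet targets group {gid}")
    achieved: dict[str, float] = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        res = run(cfg)
        achieved = {gid: res.annual_catch(gid) for gid in target_catch}
        resid = {
            gid: abs(achieved[gid] - tgt) / tgt
            for gid, tgt in target_catch.items()
        }
        if all(r <= tol for r in resid.values()):
            converged = True
            break
        new_fleets = []
        for f in cfg.fleets:
            rates = dict(f.harvest_rates)
            for gid, tgt in target_catch.items():
                if gid in rates and achieved[gid] > 0:
                    # clamp each step to avoid overshooting past the stock's
                    # surplus production (which would collapse the iteration)
                    factor = min(max(tgt / achieved[gid], 0.25), 4.0)
                    rates[gid] *= factor
            new_fleets.append(
                Fleet(
                    fleet_id=f.fleet_id, harvest_rates=rates,
                    footprint=f.footprint, port=f.port, radius_km=f.radius_km,
                    spatially_resolved=f.spatially_resolved,
                )
            )
        cfg = cfg.with_fleets(new_fleets)
    residuals = {
        gid: (achieved[gid] - tgt) / tgt for gid, tgt in target_catch.items()
    }
    return CalibrationResult(
        fleets=cfg.fleets, achieved_catch=achieved, residuals=residuals,
        converged=converged, n_iter=it,
    )


# -- CSV interchange ---------------------------------------------------------

def write_fleets_csv(fleets: list[Fleet], path) -> None:
    rows = []
    for f in fleets:
        for gid, rate in f.harvest_rates.items():
            rows.append({
                "fleet_id": f.fleet_id,
                "port_lon": f.port[0] if f.port else "",
                "port_lat": f.port[1] if f.port else "",
                "radius_km": f.radius_km if f.radius_km else "",
                "box_list": ";".join(map(str, sorted(f.footprint)))
                if f.footprint else "",
                "spatial": f.spatially_resolved,
                "group_id": gid,
                "harvest_rate": rate,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fleets_csv(path) -> list[Fleet]:
    df = pd.read_csv(path, keep_default_na=False)
    fleets = []
    for fid, fdf in df.groupby("fleet_id", sort=False):
        first = fdf.iloc[0]
        boxes = str(first["box_list"])
        footprint = (
            frozenset(int(x) for x in boxes.split(";")) if boxes else None
        )
        port = None
        radius = None
        if str(first["port_lon"]) != "":
            port = (float(first["port_lon"]), float(first["port_lat"]))
            radius = float(first["radius_km"])
        fleets.append(
            Fleet(
                fleet_id=str(fid),
                harvest_rates={
                    str(r["group_id"]): float(r["harvest_rate"])
                    for _, r in fdf.iterrows()
                },
                footprint=footprint,
                port=port,
                radius_km=radius,
                spatially_resolved=str(first["spatial"]).lower()
                in ("true", "1"),
            )
        )
    return fleets
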