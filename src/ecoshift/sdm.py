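"""Species-distribution forcing: snapshots, interpolation, masking, redistribution.

Externally supplied species distribution models (SDMs) prescribe how each
forced group's coastwide biomass is split across boxes at a set of snapshot
times (annual, monthly, or seasonal cadence).  Each timestep the simulator
linearly interpolates between bracketing snapshots, zeroes boxes outside the
group's knife-edge temperature tolerance, renormalizes, and redistributes
the group's totals proportionally.  Redistribution conserves coastwide
numbers-at-age (and pool biomass) exactly; it moves fish, it never creates
or destroys them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistributionSnapshot",
    "DistributionSeries",
    "ToleranceWindow",
    "SdmError",
    "AllBoxesMaskedWarning",
    "interpolate_distribution",
    "apply_tolerance_mask",
    "redistribute",
    "read_distribution_csv",
    "write_distribution_csv",
]

PROPORTION_SUM_TOL = 1e-9


class SdmError(ValueError):
    pass


class AllBoxesMaskedWarning(UserWarning):
    """Emitted when a tolerance window excludes every box (fallback applied)."""


@dataclass(frozen=True)
class ToleranceWindow:
    """Knife-edge thermal tolerance (degC).  Occupancy outside is zeroed."""

    t_min: float = 4.0
    t_max: float = 30.0

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise SdmError("tolerance window requires t_min < t_max")


@dataclass
class DistributionSnapshot:
    """Per-box proportions of coastwide biomass for one group at one time."""

    group_id: str
    time: float  # decimal year
    proportions: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0):
            raise SdmError(f"{self.group_id} @ {self.time}: negative proportion")
        if abs(p.sum() - 1.0) > PROPORTION_SUM_TOL:
            raise SdmError(
                f"{self.group_id} @ {self.time}: proportions sum to {p.sum()!r}, not 1"
            )
        self.proportions = p


@dataclass
class DistributionSeries:
    """Time-ordered distribution snapshots for one group."""

    group_id: str
    snapshots: list[DistributionSnapshot]
    cadence: str = "annual"  # {annual, monthly, seasonal}

    def __post_init__(self):
        if not self.snapshots:
            raise SdmError(f"{self.group_id}: need at least one snapshot")
        times = [s.time for s in self.snapshots]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SdmError(f"{self.group_id}: snapshot times must strictly increase")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def pinned_to_first(self) -> "DistributionSeries":
        """A static series holding the first snapshot only."""
        return DistributionSeries(
            group_id=self.group_id, snapshots=[self.snapshots[0]], cadence=self.cadence
        )


def interpolate_distribution(series: DistributionSeries, t: float) -> np.ndarray:
    """Proportions at decimal year ``t``.

    Linear interpolation between bracketing snapshots, renormalized to sum to
    one; constant extrapolation before the first and after the last snapshot.
    """
    times = series.times
    snaps = series.snapshots
    if t <= times[0]:
        return snaps[0].proportions.copy()
    if t >= times[-1]:
        return snaps[-1].proportions.copy()
    j = int(np.searchsorted(times, t, side="right"))
    t0, t1 = times[j - 1], times[j]
    w = (t - t0) / (t1 - t0)
    p = (1.0 - w) * snaps[j - 1].proportions + w * snaps[j].proportions
    return p / p.sum()


def apply_tolerance_mask(
    proportions: np.ndarray,
    temperature_field: np.ndarray,
    window: ToleranceWindow,
    group_id: str = "?",
) -> np.ndarray:
    """Zero boxes outside the thermal window and renormalize.

    If the window would exclude every occupied box, the unmasked proportions
    are returned unchanged and an :class:`AllBoxesMaskedWarning` is emitted —
    tolerances exist to rule out grossly wrong distributions, not to
    extirpate a group.
    """
    p = np.asarray(proportions, dtype=float)
    temp = np.asarray(temperature_field, dtype=float)
    if p.shape != temp.shape:
        raise SdmError("proportions and temperature field must cover the same boxes")
    ok = (temp >= window.t_min) & (temp <= window.t_max)
    masked = np.where(ok, p, 0.0)
    total = masked.sum()
    if total <= 0.0:
        warnings.warn(
            f"group {group_id}: all boxes outside tolerance window; "
            "keeping unmasked distribution",
            AllBoxesMaskedWarning,
            stacklevel=2,
        )
        return p.copy()
    return masked / total


def redistribute(state, proportions: np.ndarray):
    """Move a group's coastwide totals to match target proportions.

    For an age-structured group every age bin's coastwide total is spread as
    ``numbers(box, a) = p(box) * total(a)``; weights-at-age are already a
    single coastwide vector, so they are unchanged.  Pool groups redistribute
    biomass identically.  Returns a new state; coastwide totals per age are
    conserved to floating-point rounding.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise SdmError("proportions must be non-negative")
    s = p.sum()
    if abs(s - 1.0) > 1e-6:
        raise SdmError(f"proportions sum to {s!r}, not 1")
    p = p / s
    return state.with_distribution(p)


# -- CSV interchange ---------------------------------------------------------

def write_distribution_csv(series_map: dict[str, DistributionSeries], path) -> None:
    """Long-format CSV: group_id, time, box_id, proportion."""
    rows = []
    for gid, series in series_map.items():
        for snap in series.snapshots:
            for b, p in enumerate(snap.proportions):
                rows.append((gid, snap.time, b, p, series.cadence))
    pd.DataFrame(
        rows, columns=["group_id", "time", "box_id", "proportion", "cadence"]
    ).to_csv(path, index=False)


def read_distribution_csv(path) -> dict[str, DistributionSeries]:
    """Read the long-format CSV, validating the per-(group, time) sum."""
    df = pd.read_csv(path)
    out: dict[str, DistributionSeries] = {}
    for gid, gdf in df.groupby("group_id", sort=False):
        cadence = str(gdf["cadence"].iloc[0]) if "cadence" in gdf else "annual"
        snaps = []
        for t, tdf in gdf.groupby("time", sort=True):
            tdf = tdf.sort_values("box_id")
            if list(tdf["box_id"]) != list(range(len(tdf))):
                raise SdmError(f"{gid} @ {t}: box ids not contiguous from 0")
            snaps.append(
                DistributionSnapshot(
                    group_id=str(gid), time=float(t),
                    proportions=tdf["proportion"].to_numpy(),
                )
            )
        out[str(gid)] = DistributionSeries(
            group_id=str(gid), snapshots=snaps, cadence=cadence
        )
    return out
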