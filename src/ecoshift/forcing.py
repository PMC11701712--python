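"""Per-box ocean temperature forcing.

Two kinds of forcing drive the simulator:

* a *recycled baseline*: one climatological year of per-box temperatures
  repeated for every simulated year, which removes interannual variability
  while keeping the seasonal cycle and spatial gradients; and
* *delta-downscaled projections*: the same climatology plus an additive,
  per-year, per-box warming anomaly from a named earth-system-model source
  (annual step changes relative to the baseline period).

Biological rates respond to temperature through an exponential Q10 scalar,
``q10 ** ((T - T_ref) / 10)``, which doubles every 10 degC above the 15 degC
reference when ``q10 = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ClimatologyYear",
    "EsmDeltaSeries",
    "ForcingSeries",
    "ForcingError",
    "recycle_baseline",
    "delta_downscale",
    "temperature_scalar",
]

#: Default Q10 exponent base for metabolic rate scaling.
DEFAULT_Q10 = 2.0
#: Reference temperature (degC) at which the scalar equals one.
DEFAULT_T_REF = 15.0


class ForcingError(ValueError):
    pass


@dataclass
class ClimatologyYear:
    """One climatological year of per-box temperature.

    ``temperature`` has shape (timesteps_per_year, n_boxes), degC.
    Optional salinity (psu) is carried but unused by default.
    """

    temperature: np.ndarray
    salinity: np.ndarray | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.temperature.ndim != 2:
            raise ForcingError("climatology temperature must be (timestep, box)")
        if not np.all(np.isfinite(self.temperature)):
            raise ForcingError("climatology contains non-finite values")
        if self.timesteps_per_year < 1:
            raise ForcingError("timesteps_per_year must be >= 1")

    @property
    def timesteps_per_year(self) -> int:
        return self.temperature.shape[0]

    @property
    def n_boxes(self) -> int:
        return self.temperature.shape[1]


@dataclass
class EsmDeltaSeries:
    """Additive per-year, per-box temperature anomalies for one ESM source.

    ``deltas`` has shape (n_years, n_boxes), degC relative to baseline;
    ``start_year`` is the calendar year of row 0.
    """

    source_name: str
    start_year: int
    deltas: np.ndarray

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.ndim != 2:
            raise ForcingError("deltas must be (year, box)")
        if not np.all(np.isfinite(self.deltas)):
            raise ForcingError("deltas contain non-finite values")

    @property
    def n_years(self) -> int:
        return self.deltas.shape[0]

    def year_index(self, year: int) -> int:
        i = year - self.start_year
        if not (0 <= i < self.n_years):
            raise ForcingError(
                f"delta source {self.source_name!r} does not cover year {year}"
            )
        return i


@dataclass
class ForcingSeries:
    """Per-box temperature over a full simulation span.

    ``temperature`` has shape (n_years * timesteps_per_year, n_boxes).
    """

    temperature: np.ndarray
    timesteps_per_year: int
    start_year: int
    source_name: str = "baseline"

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.temperature.ndim != 2:
            raise ForcingError("forcing temperature must be (timestep, box)")
        if self.temperature.shape[0] % self.timesteps_per_year != 0:
            raise ForcingError("series length must be years * timesteps_per_year")
        if not np.all(np.isfinite(self.temperature)):
            raise ForcingError("forcing contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.temperature.shape[0]

    @property
    def n_years(self) -> int:
        return self.n_steps // self.timesteps_per_year

    @property
    def n_boxes(self) -> int:
        return self.temperature.shape[1]

    def at_step(self, step: int) -> np.ndarray:
        return self.temperature[step]

    def annual_means(self) -> np.ndarray:
        """Per-year, per-box mean temperature, shape (n_years, n_boxes)."""
        return self.temperature.reshape(
            self.n_years, self.timesteps_per_year, self.n_boxes
        ).mean(axis=1)

    # -- interchange ---------------------------------------------------------
    def to_xarray(self) -> xr.Dataset:
        tpy = self.timesteps_per_year
        time = self.start_year + np.arange(self.n_steps) / tpy
        return xr.Dataset(
            {"temperature": (("time", "box"), self.temperature)},
            coords={"time": time, "box": np.arange(self.n_boxes)},
            attrs={
                "source_name": self.source_name,
                "timesteps_per_year": tpy,
                "start_year": self.start_year,
                "units": "degC",
            },
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time, box_id, temperature) table."""
        return (
            self.to_xarray()["temperature"]
            .to_dataframe()
            .reset_index()
            .rename(columns={"box": "box_id"})
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "source_name", self.source_name)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, timesteps_per_year: int | None = None) -> "ForcingSeries":
        df = pd.read_csv(path)
        source = str(df["source_name"].iloc[0]) if "source_name" in df else "baseline"
        wide = df.pivot(index="time", columns="box_id", values="temperature")
        times = wide.index.to_numpy()
        if timesteps_per_year is None:
            # infer from the time grid spacing (time is in decimal years)
            timesteps_per_year = int(round(1.0 / np.diff(times).min()))
        return cls(
            temperature=wide.to_numpy(),
            timesteps_per_year=timesteps_per_year,
            start_year=int(round(times[0])),
            source_name=source,
        )


def recycle_baseline(
    clim: ClimatologyYear, n_years: int, start_year: int = 2013,
    source_name: str = "baseline",
) -> ForcingSeries:
    """Repeat one climatological year for ``n_years`` simulated years."""
    if n_years < 1:
        raise ForcingError("n_years must be >= 1")
    temp = np.tile(clim.temperature, (n_years, 1))
    return ForcingSeries(
        temperature=temp,
        timesteps_per_year=clim.timesteps_per_year,
        start_year=start_year,
        source_name=source_name,
    )


def delta_downscale(
    clim: ClimatologyYear,
    deltas: EsmDeltaSeries,
    years: range,
) -> ForcingSeries:
    """Climatology plus annual step-change anomalies.

    ``T(box, t in year y) = clim(box, phase(t)) + delta(y, box)``; the delta
    is constant within each year (applied as a step at the year boundary), so
    the seasonal cycle shape is preserved exactly.
    """
    if len(years) < 1:
        raise ForcingError("years range is empty")
    tpy = clim.timesteps_per_year
    blocks = []
    for y in years:
        d = deltas.deltas[deltas.year_index(y)]
        if d.shape[0] != clim.n_boxes:
            raise ForcingError("delta/climatology box count mismatch")
        blocks.append(clim.temperature + d[None, :])
    return ForcingSeries(
        temperature=np.vstack(blocks),
        timesteps_per_year=tpy,
        start_year=years.start,
        source_name=deltas.source_name,
    )


def temperature_scalar(
    t_water, q10: float = DEFAULT_Q10, t_ref: float = DEFAULT_T_REF
):
    """Q10 metabolic rate scalar: ``q10 ** ((t_water - t_ref) / 10)``.

    Strictly increasing in ``t_water``; equals 1 at the reference temperature
    and ``q10`` at ``t_ref + 10``.  Accepts scalars or arrays.
    """
    t = np.asarray(t_water, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ForcingError("t_water must be finite")
    if q10 <= 0:
        raise ForcingError("q10 must be positive")
    out = np.power(q10, (t - t_ref) / 10.0)
    if np.isscalar(t_water) or np.ndim(t_water) == 0:
        return float(out)
    return out
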