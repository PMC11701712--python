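"""End-of-century contrast metrics across scenarios.

All contrasts are percent differences of end-of-century means (final six
simulated years by default, e.g. 2095-2100 of an 87-year run) relative to
the Base scenario: biomass by group, abundance and weight by group x age,
biomass by box (map-style), and catch by fleet x group.  Cells whose Base
value is zero are reported as missing, never infinite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenarios import BASE_NAME, ScenarioResult

__all__ = [
    "MetricsError",
    "end_of_century_mean",
    "relative_change",
    "contrast_tables",
    "mortality_decomposition",
    "plot_contrast_heatmap",
]

#: Number of final simulated years averaged for end-of-century values.
DEFAULT_WINDOW_YEARS = 6


class MetricsError(ValueError):
    pass


def end_of_century_mean(
    series: np.ndarray,
    time: np.ndarray,
    window_years: tuple[float, float] | None = None,
) -> float | np.ndarray:
    """Arithmetic mean of a time-indexed series over an inclusive year window.

    ``series`` is indexed on its first axis by ``time`` (decimal years).
    Default window: the final :data:`DEFAULT_WINDOW_YEARS` years of the
    series.
    """
    series = np.asarray(series)
    time = np.asarray(time)
    if series.shape[0] != time.shape[0]:
        raise MetricsError("series and time must align on the first axis")
    if window_years is None:
        window_years = (time[-1] - DEFAULT_WINDOW_YEARS, time[-1])
    lo, hi = window_years
    mask = (time >= lo) & (time <= hi)
    if not mask.any():
        raise MetricsError(f"no samples in window [{lo}, {hi}]")
    return series[mask].mean(axis=0)


def relative_change(value, base_value):
    """Percent difference ``100 (value - base) / base``; NaN where base is 0."""
    value = np.asarray(value, dtype=float)
    base = np.asarray(base_value, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(base != 0, 100.0 * (value - base) / np.where(
            base != 0, base, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _only_results(results: dict) -> dict[str, ScenarioResult]:
    return {k: v for k, v in results.items() if isinstance(v, ScenarioResult)}


def contrast_tables(
    results: dict,
    window_years: tuple[float, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Percent-change tables vs Base for a map of scenario results.

    Returns DataFrames keyed ``biomass_by_group``, ``abundance_by_group_age``,
    ``weight_by_group_age``, ``biomass_by_box`` and ``catch_by_fleet_group``;
    rows are groups (or group x age / group x box / fleet x group), columns
    are scenario names, the Base column is identically zero.
    """
    results = _only_results(results)
    if BASE_NAME not in results:
        raise MetricsError(f"results must include the {BASE_NAME!r} scenario")
    base = results[BASE_NAME]
    names = list(results)

    def eoc(res: ScenarioResult, series):
        return end_of_century_mean(series, res.time, window_years)

    def eoc_flux(res: ScenarioResult, series):
        # per-step fluxes align with time[1:] (the step's end boundary)
        return end_of_century_mean(series, res.time[1:], window_years)

    groups = list(base.group_kinds)
    age_groups = [g for g in groups if base.group_kinds[g] == "age_structured"]

    tables: dict[str, pd.DataFrame] = {}

    biom = {
        name: [
            relative_change(eoc(r, r.biomass_total(g)),
                            eoc(base, base.biomass_total(g)))
            for g in groups
        ]
        for name, r in results.items()
    }
    tables["biomass_by_group"] = pd.DataFrame(biom, index=groups)[names]

    idx = pd.MultiIndex.from_tuples(
        [(g, a) for g in age_groups
         for a in range(base.numbers[g].shape[1])],
        names=["group_id", "age_bin"],
    )
    abund, wgt = {}, {}
    for name, r in results.items():
        acol, wcol = [], []
        for g in age_groups:
            acol.extend(
                relative_change(eoc(r, r.numbers[g]), eoc(base, base.numbers[g]))
            )
            wcol.extend(
                relative_change(eoc(r, r.weight[g]), eoc(base, base.weight[g]))
            )
        abund[name], wgt[name] = acol, wcol
    tables["abundance_by_group_age"] = pd.DataFrame(abund, index=idx)[names]
    tables["weight_by_group_age"] = pd.DataFrame(wgt, index=idx)[names]

    bidx = pd.MultiIndex.from_tuples(
        [(g, b) for g in groups for b in range(base.biomass_box[g].shape[1])],
        names=["group_id", "box_id"],
    )
    bbox = {
        name: np.concatenate([
            relative_change(eoc(r, r.biomass_box[g]),
                            eoc(base, base.biomass_box[g]))
            for g in groups
        ])
        for name, r in results.items()
    }
    tables["biomass_by_box"] = pd.DataFrame(bbox, index=bidx)[names]

    fidx = pd.MultiIndex.from_tuples(
        [(f, g) for f in base.fleet_ids for g in groups],
        names=["fleet_id", "group_id"],
    )
    catch = {}
    for name, r in results.items():
        col = []
        for f in base.fleet_ids:
            fi = base.fleet_ids.index(f)
            for g in groups:
                col.append(
                    relative_change(
                        eoc_flux(r, r.catch[g][:, fi]),
                        eoc_flux(base, base.catch[g][:, fi]),
                    )
                )
        catch[name] = col
    tables["catch_by_fleet_group"] = pd.DataFrame(catch, index=fidx)[names]
    return tables


def mortality_decomposition(result: ScenarioResult, group_id: str) -> pd.DataFrame:
    """Annual fishing and summed predation mortality by age bin (tonnes).

    Aggregates the per-step mortality ledger over boxes and within years;
    long format with columns (year, age_bin, fishing, predation, linear).
    """
    if group_id not in result.ledgers:
        raise MetricsError(f"unknown group {group_id!r}")
    led = result.ledgers[group_id]
    tpy = result.timesteps_per_year
    n_comp = led.predation.shape[1]

    def annual(arr):
        return arr.reshape(-1, tpy, n_comp).sum(axis=1)

    fish, pred, lin = annual(led.fishing), annual(led.predation), annual(led.linear)
    rows = []
    for yi in range(fish.shape[0]):
        for a in range(n_comp):
            rows.append(
                (result.start_year + yi, a, fish[yi, a], pred[yi, a], lin[yi, a])
            )
    return pd.DataFrame(
        rows, columns=["year", "age_bin", "fishing", "predation", "linear"]
    )


def plot_contrast_heatmap(table: pd.DataFrame, title: str = "", ax=None):
    """Render a contrast table as a diverging heatmap (rows x scenarios)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.2 * len(table.columns) + 2, 0.3 * len(table) + 1.5)
        )
    data = table.to_numpy(dtype=float)
    lim = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(table)), [str(i) for i in table.index])
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="% change vs Base")
    return ax
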