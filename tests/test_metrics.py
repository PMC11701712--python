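"""End-of-century means, percent contrasts and the figure-style tables."""

import numpy as np
import pandas as pd
import pytest

from ecoshift.metrics import (MetricsError, contrast_tables,
                              end_of_century_mean, mortality_decomposition,
                              relative_change)


class TestEndOfCenturyMean:
    def test_constant_series(self):
        t = np.linspace(2013, 2100, 100)
        assert end_of_century_mean(np.full(100, 5.0), t) == pytest.approx(5.0)

    def test_linear_series_mean_is_midpoint(self):
        t = np.linspace(2094, 2100, 601)
        series = 2.0 * (t - 2094.0)
        out = end_of_century_mean(series, t, window_years=(2095, 2100))
        mid = 2.0 * (0.5 * (2095 + 2100) - 2094)
        assert out == pytest.approx(mid, rel=1e-6)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        t = 2013 + np.arange(5000) / 73.0
        series = rng.normal(size=5000)
        mask = (t >= t[-1] - 6) & (t <= t[-1])
        assert end_of_century_mean(series, t) == pytest.approx(
            series[mask].sum() / mask.sum()
        )

    def test_refinement_invariance_for_smooth_series(self):
        def series(tpy):
            t = 2013 + np.arange(20 * tpy) / tpy
            return end_of_century_mean(np.sin(0.1 * t) + t / 50, t,
                                       window_years=(2027, 2032))

        assert series(73) == pytest.approx(series(730), rel=1e-3)

    def test_empty_window_rejected(self):
        t = np.linspace(2013, 2020, 10)
        with pytest.raises(MetricsError):
            end_of_century_mean(np.ones(10), t, window_years=(2095, 2100))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "value,base,expected", [(85, 100, -15.0), (7, 7, 0.0), (200, 100, 100.0)]
    )
    def test_examples(self, value, base, expected):
        assert relative_change(value, base) == pytest.approx(expected)

    def test_zero_base_is_missing_not_infinite(self):
        assert np.isnan(relative_change(5.0, 0.0))
        arr = relative_change(np.array([1.0, 2.0]), np.array([0.0, 4.0]))
        assert np.isnan(arr[0]) and arr[1] == pytest.approx(-50.0)


class TestContrastTables:
    def test_all_scenarios_equal_base_gives_zero_tables(self, base_min):
        results = {"Base": base_min, "SpatialShift": base_min,
                   "Warming": base_min}
        tables = contrast_tables(results)
        for name, tab in tables.items():
            vals = tab.to_numpy(dtype=float)
            assert np.nanmax(np.abs(vals)) == pytest.approx(0.0), name

    def test_base_column_identically_zero(self, base_min, shift_min):
        tables = contrast_tables({"Base": base_min, "SpatialShift": shift_min})
        for tab in tables.values():
            base_col = tab["Base"].to_numpy(dtype=float)
            finite = base_col[np.isfinite(base_col)]
            np.testing.assert_allclose(finite, 0.0, atol=1e-9)

    def test_shifted_group_biomass_cell_sign(self, base_min, shift_min):
        # the poleward-shifting stock escapes its only fleet; biomass rises
        tables = contrast_tables({"Base": base_min, "SpatialShift": shift_min})
        cell = tables["biomass_by_group"].loc["forage", "SpatialShift"]
        assert np.isfinite(cell) and cell != 0.0

    def test_labels_match_groups_and_scenarios(self, base_min, shift_min):
        results = {"Base": base_min, "SpatialShift": shift_min}
        tables = contrast_tables(results)
        assert list(tables["biomass_by_group"].columns) == list(results)
        assert set(tables["biomass_by_group"].index) == \
            set(base_min.group_kinds)
        fleet_rows = tables["catch_by_fleet_group"].index
        assert set(fleet_rows.get_level_values("fleet_id")) == \
            set(base_min.fleet_ids)

    def test_missing_base_rejected(self, shift_min):
        with pytest.raises(MetricsError):
            contrast_tables({"SpatialShift": shift_min})


class TestMortalityDecomposition:
    def test_unfished_group_has_zero_fishing(self, base_min):
        out = mortality_decomposition(base_min, "zoo")
        assert out["fishing"].abs().max() == 0.0

    def test_apex_group_has_zero_predation(self, base_cps):
        out = mortality_decomposition(base_cps, "piscivore")
        assert out["predation"].abs().max() == 0.0

    def test_components_reconcile_with_ledger(self, base_min):
        # independent aggregation oracle over raw per-step ledger entries
        out = mortality_decomposition(base_min, "forage")
        led = base_min.ledgers["forage"]
        tpy = base_min.timesteps_per_year
        for comp, arr in (("fishing", led.fishing), ("predation", led.predation)):
            brute = arr.reshape(-1, tpy, arr.shape[1]).sum(axis=1)
            table = out.pivot(index="year", columns="age_bin", values=comp)
            np.testing.assert_allclose(table.to_numpy(), brute, rtol=1e-12)

    def test_unknown_group_rejected(self, base_min):
        with pytest.raises(MetricsError):
            mortality_decomposition(base_min, "krakens")


def test_heatmap_renders(base_min, shift_min, tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from ecoshift.metrics import plot_contrast_heatmap

    tables = contrast_tables({"Base": base_min, "SpatialShift": shift_min})
    ax = plot_contrast_heatmap(tables["biomass_by_group"], title="biomass")
    ax.figure.savefig(tmp_path / "heatmap.png")
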