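"""Fleet footprints, additive rates, realized fishing mortality, and
harvest-rate calibration."""

from dataclasses import replace

import numpy as np
import pytest

from ecoshift.fisheries import (CalibrationResult, EmptyFootprintWarning,
                                FisheriesError, Fleet, calibrate_harvest_rates,
                                fleet_fishing_rate, footprint_from_port,
                                read_fleets_csv, realized_F, write_fleets_csv)
from ecoshift.geometry import build_synthetic_geometry


@pytest.fixture(scope="module")
def geom():
    return build_synthetic_geometry(3, 2, seed=0)


class TestFootprintFromPort:
    def test_huge_radius_covers_all_boxes(self, geom):
        port = geom.boxes[0].centroid()
        fp = footprint_from_port(port, 1e5, geom)
        assert fp == frozenset(range(geom.n_boxes))

    def test_tiny_radius_at_centroid_hits_that_box_only(self, geom):
        for b in geom.boxes:
            fp = footprint_from_port(b.centroid(), 0.5, geom)
            assert fp == frozenset({b.id})

    def test_port_on_shared_edge_hits_both_boxes(self, geom):
        # brute-force oracle: boxes whose vertices lie within the disc
        b0, b1 = geom.boxes[0], geom.boxes[2]  # vertically adjacent (rows)
        shared_lat = max(y for _, y in b0.polygon)
        lon_mid = 0.5 * (min(x for x, _ in b0.polygon)
                         + max(x for x, _ in b0.polygon))
        port = (lon_mid, shared_lat)
        fp = footprint_from_port(port, 10.0, geom)
        assert {b0.id, b1.id} <= fp

    def test_far_away_port_warns_and_returns_empty(self, geom):
        with pytest.warns(EmptyFootprintWarning):
            fp = footprint_from_port((60.0, -40.0), 5.0, geom)
        assert fp == frozenset()

    def test_rejects_nonpositive_radius(self, geom):
        with pytest.raises(FisheriesError):
            footprint_from_port((0.0, 0.0), 0.0, geom)


class TestFleetFishingRate:
    def test_outside_all_footprints_zero(self, geom):
        fleets = [Fleet("a", {"g": 1e-3}, footprint=frozenset({0}))]
        assert fleet_fishing_rate(fleets, "g", 5, geom) == 0.0

    def test_overlapping_fleets_add(self, geom):
        fleets = [
            Fleet("a", {"g": 1e-3}, footprint=frozenset({0, 1})),
            Fleet("b", {"g": 2e-3}, footprint=frozenset({1, 2})),
        ]
        assert fleet_fishing_rate(fleets, "g", 1, geom) == pytest.approx(3e-3)

    def test_group_not_in_any_portfolio_zero_everywhere(self, geom):
        fleets = [Fleet("a", {"g": 1e-3}, footprint=frozenset({0, 1}))]
        for b in range(geom.n_boxes):
            assert fleet_fishing_rate(fleets, "other", b, geom) == 0.0

    def test_non_spatial_fleet_covers_domain(self, geom):
        fleets = [Fleet("a", {"g": 1e-3}, spatially_resolved=False)]
        for b in range(geom.n_boxes):
            assert fleet_fishing_rate(fleets, "g", b, geom) == pytest.approx(1e-3)


class _ResultStub:
    """Minimal stand-in (synthetic) for a ScenarioResult in rate algebra."""

    def __init__(self, catch, biomass, dt_days=1.0):
        self._catch = np.asarray(catch, dtype=float)
        self._biomass = np.asarray(biomass, dtype=float)
        self.dt_days = dt_days

    def catch_total(self, gid):
        return self._catch

    def biomass_total(self, gid):
        return self._biomass


class TestRealizedF:
    def test_whole_stock_inside_footprint_equals_nominal(self):
        # catch per step = B * (1 - exp(-F dt)) ~ B F dt for small F
        f = 1e-4
        b = 1000.0
        catch = np.full(10, b * (1 - np.exp(-f)))
        stub = _ResultStub(catch, np.full(11, b))
        assert realized_F(stub, "g") == pytest.approx(f, rel=1e-3)

    def test_whole_stock_outside_footprint_is_zero(self):
        stub = _ResultStub(np.zeros(10), np.full(11, 1000.0))
        assert realized_F(stub, "g") == 0.0

    def test_half_overlap_gives_half_nominal(self):
        # oracle: direct computation from the definition
        f = 1e-4
        b = 1000.0
        catch = np.full(10, 0.5 * b * f)  # only half the biomass is fished
        stub = _ResultStub(catch, np.full(11, b))
        assert realized_F(stub, "g") == pytest.approx(0.5 * f, rel=1e-3)

    def test_zero_biomass_returns_nan(self):
        stub = _ResultStub(np.zeros(10), np.zeros(11))
        assert np.isnan(realized_F(stub, "g"))


class TestCalibration:
    def test_fixed_point_keeps_rates(self, minimal_cfg):
        cfg = replace(minimal_cfg, n_years=8)
        from ecoshift.scenarios import base_spec, run_scenario

        achieved = run_scenario(base_spec(cfg), cfg).annual_catch("forage")
        out = calibrate_harvest_rates({"forage": achieved}, cfg, tol=0.02,
                                      max_iter=3)
        assert isinstance(out, CalibrationResult)
        assert out.converged and out.n_iter == 1
        assert out.fleets[0].harvest_rates["forage"] == pytest.approx(
            cfg.fleets[0].harvest_rates["forage"]
        )

    def test_doubled_target_converges_within_tolerance(self, minimal_cfg):
        # linear regime: a light harvest rate, far below surplus production
        light = [replace(f, harvest_rates={"forage": 1e-4})
                 for f in minimal_cfg.fleets]
        cfg = replace(minimal_cfg, n_years=8, fleets=light)
        from ecoshift.scenarios import base_spec, run_scenario

        achieved = run_scenario(base_spec(cfg), cfg).annual_catch("forage")
        out = calibrate_harvest_rates({"forage": 2 * achieved}, cfg, tol=0.05,
                                      max_iter=6)
        assert out.converged
        assert abs(out.residuals["forage"]) <= 0.05
        assert out.fleets[0].harvest_rates["forage"] > \
            cfg.fleets[0].harvest_rates["forage"]

    def test_target_for_unfished_group_rejected(self, minimal_cfg):
        with pytest.raises(FisheriesError):
            calibrate_harvest_rates({"zoo": 100.0}, minimal_cfg)


def test_fleet_csv_round_trip(tmp_path):
    fleets = [
        Fleet("port_a", {"g1": 1e-3, "g2": 2e-3}, port=(-120.0, 34.0),
              radius_km=150.0),
        Fleet("boxes_b", {"g1": 5e-4}, footprint=frozenset({0, 3, 4})),
        Fleet("wide_c", {"g2": 1e-4}, spatially_resolved=False),
    ]
    path = tmp_path / "fleets.csv"
    write_fleets_csv(fleets, path)
    back = read_fleets_csv(path)
    assert [f.fleet_id for f in back] == ["port_a", "boxes_b", "wide_c"]
    assert back[0].port == (-120.0, 34.0)
    assert back[0].harvest_rates == fleets[0].harvest_rates
    assert back[1].footprint == frozenset({0, 3, 4})
    assert back[2].spatially_resolved is False
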