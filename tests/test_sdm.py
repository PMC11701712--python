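"""Distribution interpolation, tolerance masking and mass-conserving
redistribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoshift.ecology import GroupState
from ecoshift.sdm import (AllBoxesMaskedWarning, DistributionSeries,
                          DistributionSnapshot, SdmError, ToleranceWindow,
                          apply_tolerance_mask, interpolate_distribution,
                          read_distribution_csv, redistribute,
                          write_distribution_csv)


def series_two_snapshots():
    return DistributionSeries(
        group_id="g",
        snapshots=[
            DistributionSnapshot("g", 0.0, np.array([1.0, 0.0])),
            DistributionSnapshot("g", 1.0, np.array([0.0, 1.0])),
        ],
    )


class TestInterpolation:
    def test_midpoint(self):
        p = interpolate_distribution(series_two_snapshots(), 0.5)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_snapshot_time_returns_snapshot(self):
        p = interpolate_distribution(series_two_snapshots(), 1.0)
        np.testing.assert_allclose(p, [0.0, 1.0])

    def test_constant_extrapolation(self):
        s = series_two_snapshots()
        np.testing.assert_allclose(interpolate_distribution(s, -3.0), [1, 0])
        np.testing.assert_allclose(interpolate_distribution(s, 9.0), [0, 1])

    def test_interpolant_always_sums_to_one(self):
        s = series_two_snapshots()
        for t in np.linspace(-1, 2, 17):
            assert interpolate_distribution(s, t).sum() == pytest.approx(1.0)

    def test_snapshot_validation(self):
        with pytest.raises(SdmError):
            DistributionSnapshot("g", 0.0, np.array([0.6, 0.6]))
        with pytest.raises(SdmError):
            DistributionSnapshot("g", 0.0, np.array([-0.1, 1.1]))
        with pytest.raises(SdmError):
            DistributionSeries(group_id="g", snapshots=[])


class TestToleranceMask:
    def test_all_within_window_unchanged(self):
        p = np.array([0.3, 0.7])
        out = apply_tolerance_mask(p, np.array([10.0, 20.0]),
                                   ToleranceWindow(4, 30))
        np.testing.assert_allclose(out, p)

    def test_masked_box_renormalizes(self):
        out = apply_tolerance_mask(
            np.array([0.5, 0.5]), np.array([10.0, 31.0]),
            ToleranceWindow(4, 30),
        )
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_all_masked_falls_back_with_warning(self):
        p = np.array([0.5, 0.5])
        with pytest.warns(AllBoxesMaskedWarning):
            out = apply_tolerance_mask(p, np.array([35.0, 35.0]),
                                       ToleranceWindow(4, 30))
        np.testing.assert_allclose(out, p)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_surviving_ratio_preserved(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        temps = rng.uniform(0, 40, size=6)
        window = ToleranceWindow(4, 30)
        ok = (temps >= 4) & (temps <= 30)
        if ok.sum() < 2 or p[ok].sum() == 0:
            return
        out = apply_tolerance_mask(p, temps, window)
        idx = np.flatnonzero(ok & (p > 0))
        if len(idx) >= 2:
            i, j = idx[0], idx[1]
            assert out[i] / out[j] == pytest.approx(p[i] / p[j], rel=1e-9)

    def test_window_requires_min_below_max(self):
        with pytest.raises(SdmError):
            ToleranceWindow(30, 4)


def random_age_state(rng, n_boxes=4, n_ages=10):
    return GroupState(
        group_id="g", kind="age_structured",
        numbers=rng.uniform(0, 1e6, size=(n_boxes, n_ages)),
        weight_at_age=rng.uniform(1, 100, size=n_ages),
    )


class TestRedistribute:
    def test_uniform_proportions_split_evenly(self):
        state = GroupState(
            group_id="g", kind="age_structured",
            numbers=np.array([[100.0], [0.0], [0.0], [0.0]]).repeat(10, axis=1),
            weight_at_age=np.ones(10),
        )
        out = redistribute(state, np.full(4, 0.25))
        np.testing.assert_allclose(out.numbers[:, 0], 25.0)

    def test_current_distribution_is_fixed_point(self):
        # a state whose every age bin already follows p is unchanged by
        # redistribution to p
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4))
        totals = rng.uniform(1e3, 1e6, size=10)
        state = GroupState(
            group_id="g", kind="age_structured",
            numbers=p[:, None] * totals[None, :],
            weight_at_age=rng.uniform(1, 100, size=10),
        )
        out = redistribute(state, p)
        np.testing.assert_allclose(out.numbers, state.numbers, rtol=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_per_age_totals_conserved(self, seed):
        # oracle: brute-force summation over boxes before and after
        rng = np.random.default_rng(seed)
        state = random_age_state(rng)
        p = rng.dirichlet(np.ones(4))
        out = redistribute(state, p)
        before = state.numbers.sum(axis=0)
        after = out.numbers.sum(axis=0)
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        state = random_age_state(rng)
        p = rng.dirichlet(np.ones(4))
        once = redistribute(state, p)
        twice = redistribute(once, p)
        np.testing.assert_allclose(twice.numbers, once.numbers, rtol=1e-12)

    def test_pool_biomass_redistributes_identically(self):
        state = GroupState(group_id="z", kind="pool",
                           biomass=np.array([10.0, 30.0]))
        out = redistribute(state, np.array([0.5, 0.5]))
        np.testing.assert_allclose(out.biomass, [20.0, 20.0])

    def test_invalid_proportions_rejected(self):
        rng = np.random.default_rng(4)
        state = random_age_state(rng)
        with pytest.raises(SdmError):
            redistribute(state, np.array([0.5, 0.6, 0.2, 0.2]))


def test_distribution_csv_round_trip(tmp_path):
    series = {"g": series_two_snapshots()}
    path = tmp_path / "sdm.csv"
    write_distribution_csv(series, path)
    back = read_distribution_csv(path)
    assert list(back) == ["g"]
    assert back["g"].cadence == "annual"
    for a, b in zip(back["g"].snapshots, series["g"].snapshots):
        assert a.time == b.time
        np.testing.assert_allclose(a.proportions, b.proportions)
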