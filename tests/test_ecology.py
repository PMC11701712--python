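"""Elemental ecological operations: consumption, growth, mortality,
recruitment, aging, producer growth, and whole-system stepping."""

import numpy as np
import pytest

from ecoshift.ecology import (AvailabilityMatrix, Ecosystem, EcologyError,
                              FishingField, FunctionalGroupDef, GroupState,
                              MortalityLedger, PreyItem, add_recruits,
                              age_step, apply_mortality, consumption,
                              gape_filter, grow, producer_growth, recruit,
                              step_ecosystem)
from ecoshift.geometry import build_synthetic_geometry


def predator_def(clearance=1.0, imax=0.1) -> FunctionalGroupDef:
    return FunctionalGroupDef(
        group_id="pred", kind="age_structured", years_per_bin=1,
        w_ref=np.linspace(10, 100, 10), clearance_rate=clearance,
        max_ingestion=imax, gape_window=(1e-6, 1.0),
    )


class TestConsumption:
    def test_half_saturation_point(self):
        # a * A * B == I_max  ->  intake = ts * I_max / 2
        pred = predator_def(clearance=0.5, imax=0.1)
        avail = AvailabilityMatrix()
        avail.set("pred", "adult", "prey", "adult", 1.0)
        prey = [PreyItem("prey", "adult", biomass=0.2, indiv_weight=1.0)]
        out = consumption(pred, 50.0, "adult", prey, avail, t_scalar=1.0)
        assert out[0] == pytest.approx(0.05)
        out2 = consumption(pred, 50.0, "adult", prey, avail, t_scalar=2.0)
        assert out2[0] == pytest.approx(0.1)

    def test_no_available_prey_gives_zero(self):
        pred = predator_def()
        out = consumption(
            pred, 50.0, "adult",
            [PreyItem("prey", "adult", 10.0, 1.0)],
            AvailabilityMatrix(), t_scalar=1.0,
        )
        assert out[0] == 0.0

    def test_equal_prey_split_equally(self):
        # oracle: direct evaluation of the stated formula
        pred = predator_def(clearance=0.3, imax=0.2)
        avail = AvailabilityMatrix()
        avail.set("pred", "adult", "p1", "adult", 0.5)
        avail.set("pred", "adult", "p2", "adult", 0.5)
        prey = [PreyItem("p1", "adult", 4.0, 1.0),
                PreyItem("p2", "adult", 4.0, 1.0)]
        out = consumption(pred, 50.0, "adult", prey, avail, t_scalar=1.3)
        enc = 0.3 * 0.5 * 4.0
        expected = 1.3 * 0.2 * enc / (0.2 + 2 * enc)
        assert out[0] == pytest.approx(expected)
        assert out[0] == pytest.approx(out[1])
        assert out.sum() <= 1.3 * 0.2 + 1e-12

    def test_gape_excluded_prey_ignored(self):
        pred = predator_def()
        avail = AvailabilityMatrix()
        avail.set("pred", "adult", "whale", "adult", 1.0)
        prey = [PreyItem("whale", "adult", 5.0, 1e6)]  # far above gape
        out = consumption(pred, 50.0, "adult", prey, avail, t_scalar=1.0)
        assert out[0] == 0.0


class TestGapeFilter:
    @pytest.mark.parametrize(
        "pred_w,prey_w,expected",
        [
            (100.0, 1.0, 1.0),  # inside window
            (100.0, 100.0 * 1e-6, 1.0),  # exactly at lower bound (closed)
            (100.0, 60.0, 0.0),  # above max ratio 0.5
        ],
    )
    def test_window_boundaries(self, pred_w, prey_w, expected):
        assert gape_filter(pred_w, prey_w, (1e-6, 0.5)) == expected

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(EcologyError):
            gape_filter(0.0, 1.0, (0.1, 0.5))


class TestGrow:
    def test_balance_point_is_fixed(self):
        # assimilated intake == t_scalar * resp * w  ->  w unchanged
        w = 40.0
        assert grow(w, assimilated_intake=0.01 * w, respiration_coeff=0.01,
                    t_scalar=1.0, dt=0.5) == pytest.approx(w)

    def test_zero_intake_declines_linearly(self):
        w = 40.0
        out = grow(w, 0.0, respiration_coeff=0.01, t_scalar=1.0, dt=0.5)
        assert out == pytest.approx(w - 0.5 * 0.01 * w)

    def test_starvation_floor_holds(self):
        out = grow(10.0, 0.0, respiration_coeff=0.5, t_scalar=1.0, dt=10.0,
                   w_floor=5.0)
        assert out == 5.0

    def test_warming_with_saturating_prey_grows_larger_after_one_year(self):
        # integrate one year at ts=1 vs ts=2 with temperature-scaled intake
        # (the simulator's Q10 acts on ingestion, not respiration)
        def integrate(ts, days=365):
            w = 10.0
            sat_intake_per_unit = 0.004  # per day, saturated ration
            for _ in range(days):
                w = grow(w, ts * sat_intake_per_unit * 10.0,
                         respiration_coeff=0.002, t_scalar=1.0, dt=1.0)
            return w

        assert integrate(2.0) > integrate(1.0)


class TestApplyMortality:
    def test_all_rates_zero_leaves_state(self):
        b = np.array([[10.0, 5.0]])
        surv, losses, scale = apply_mortality(
            b, np.zeros_like(b), np.zeros_like(b), np.zeros_like(b), dt=0.5
        )
        assert np.all(surv == 1.0)
        assert all(np.all(v == 0) for v in losses.values())
        assert np.all(scale == 1.0)

    def test_matches_closed_form_exponential(self):
        b = np.array([[100.0]])
        f = np.array([[0.01]])
        m = np.array([[0.005]])
        surv, losses, _ = apply_mortality(b, np.zeros_like(b), f, m, dt=2.0)
        expected = np.exp(-(0.015) * 2.0)
        assert surv[0, 0] == pytest.approx(expected, rel=1e-12)
        total_loss = losses["fishing"] + losses["linear"]
        assert total_loss[0, 0] == pytest.approx(100.0 * (1 - expected))
        # attribution by rate share
        assert losses["fishing"][0, 0] / losses["linear"][0, 0] == \
            pytest.approx(2.0)

    def test_excess_demand_capped_and_scale_reported(self):
        b = np.array([[1.0]])
        demand = np.array([[100.0]])  # tonnes/day >> biomass
        surv, losses, scale = apply_mortality(
            b, demand, np.zeros_like(b), np.zeros_like(b), dt=1.0
        )
        assert losses["predation"][0, 0] <= 1.0
        assert losses["predation"][0, 0] == pytest.approx(
            demand[0, 0] * 1.0 * scale[0, 0]
        )
        assert scale[0, 0] < 0.05

    def test_negative_demand_rejected(self):
        b = np.array([[1.0]])
        with pytest.raises(EcologyError):
            apply_mortality(b, -b, np.zeros_like(b), np.zeros_like(b), dt=1.0)


def simple_stock(numbers_scale=1e6):
    w_ref = np.linspace(10, 100, 10)
    gdef = FunctionalGroupDef(
        group_id="s", kind="age_structured", years_per_bin=1,
        w_ref=w_ref, recruit_alpha=1000.0, recruit_beta=5.0,
        juvenile_adult_split_bin=2,
    )
    state = GroupState(
        group_id="s", kind="age_structured",
        numbers=np.full((2, 10), numbers_scale),
        weight_at_age=w_ref.copy(),
    )
    return gdef, state


class TestRecruit:
    def test_beverton_holt_half_point(self):
        gdef, state = simple_stock()
        _, s0 = recruit(state, gdef)
        gdef.recruit_beta = s0
        r, _ = recruit(state, gdef)
        assert r == pytest.approx(gdef.recruit_alpha / 2)

    def test_zero_spawners_zero_recruits(self):
        gdef, state = simple_stock()
        state.numbers[:] = 0.0
        r, s = recruit(state, gdef)
        assert r == 0.0 and s == 0.0

    def test_condition_multiplier_scales_spawning_quadratically(self):
        # S ~ sum maturity * N * w * (w / w_ref): w = 1.1 w_ref -> S x 1.21
        gdef, state = simple_stock()
        _, s_ref = recruit(state, gdef)
        state.weight_at_age = 1.1 * gdef.w_ref
        _, s_fat = recruit(state, gdef)
        assert s_fat / s_ref == pytest.approx(1.1 * 1.1)

    def test_recruits_added_to_first_bin_with_reference_weight(self):
        gdef, state = simple_stock()
        state.numbers[:, 0] = 0.0
        added = add_recruits(state, gdef, 500.0)
        assert state.numbers[:, 0].sum() == pytest.approx(500.0)
        assert state.weight_at_age[0] == pytest.approx(gdef.w_ref[0])
        assert added == pytest.approx(500.0 * gdef.w_ref[0] / 1e6)


class TestAgeStep:
    def test_full_cohort_shift_with_plus_group(self):
        gdef, state = simple_stock(numbers_scale=100.0)
        out = age_step(state, gdef)
        # bins 1..8 receive the full upstream cohort; plus group accumulates
        np.testing.assert_allclose(out.numbers[:, 0], 0.0)
        np.testing.assert_allclose(out.numbers[:, 5], 100.0)
        np.testing.assert_allclose(out.numbers[:, 9], 200.0)

    def test_all_zero_stays_zero(self):
        gdef, state = simple_stock()
        state.numbers[:] = 0.0
        out = age_step(state, gdef)
        assert np.all(out.numbers == 0)

    def test_fractional_promotion_rule(self):
        # years_per_bin = 2: half of each bin promotes
        w_ref = np.linspace(10, 100, 10)
        gdef = FunctionalGroupDef(
            group_id="s", kind="age_structured", years_per_bin=2, w_ref=w_ref
        )
        numbers = np.zeros((1, 10))
        numbers[0, 1] = 100.0
        state = GroupState(group_id="s", kind="age_structured",
                           numbers=numbers, weight_at_age=w_ref.copy())
        out = age_step(state, gdef)
        assert out.numbers[0, 1] == pytest.approx(50.0)
        assert out.numbers[0, 2] == pytest.approx(50.0)

    def test_total_numbers_and_biomass_conserved(self):
        gdef, state = simple_stock(numbers_scale=123.0)
        state.weight_at_age = gdef.w_ref * 1.3
        out = age_step(state, gdef)
        assert out.numbers.sum() == pytest.approx(state.numbers.sum())
        assert out.total_biomass() == pytest.approx(state.total_biomass())


class TestProducerGrowth:
    def test_at_carrying_capacity_no_change(self):
        b = np.array([100.0])
        out = producer_growth(b, 0.5, np.array([1.0]), np.array([100.0]), 0.5)
        np.testing.assert_allclose(out, b)

    def test_zero_stays_zero(self):
        out = producer_growth(np.array([0.0]), 0.5, np.array([1.0]),
                              np.array([100.0]), 0.5)
        assert out[0] == 0.0

    def test_doubled_scalar_doubles_increment_far_below_k(self):
        b = np.array([1.0])
        k = np.array([1e6])
        inc1 = producer_growth(b, 0.5, np.array([1.0]), k, 0.5) - b
        inc2 = producer_growth(b, 0.5, np.array([2.0]), k, 0.5) - b
        assert inc2[0] / inc1[0] == pytest.approx(2.0, rel=1e-4)


class TestStepEcosystem:
    def test_no_groups_is_a_no_op(self):
        geom = build_synthetic_geometry(2, 1, seed=0)
        eco = Ecosystem(
            geometry=geom, defs={}, avail=AvailabilityMatrix(), states={},
            fishing=FishingField.empty([], geom.n_boxes),
        )
        step_ecosystem(eco, np.full(geom.n_boxes, 15.0), t=2013.0, dt=0.5)
        assert eco.states == {}

    def test_single_producer_below_k_strictly_increases(self):
        geom = build_synthetic_geometry(2, 1, seed=0)
        gdef = FunctionalGroupDef(
            group_id="p", kind="producer", growth_rate=0.5,
            carrying_capacity=np.array([100.0, 100.0]),
        )
        state = GroupState(group_id="p", kind="producer",
                           biomass=np.array([10.0, 20.0]))
        eco = Ecosystem(
            geometry=geom, defs={"p": gdef}, avail=AvailabilityMatrix(),
            states={"p": state},
            fishing=FishingField.empty(["p"], geom.n_boxes),
        )
        before = eco.states["p"].biomass.copy()
        ledger = {"p": MortalityLedger(1, 1)}
        step_ecosystem(eco, np.full(2, 15.0), t=2013.0, dt=0.5,
                       ledgers=ledger)
        after = eco.states["p"].biomass
        assert np.all(after > before)
        assert ledger["p"].production[0] == pytest.approx(
            (after - before).sum()
        )
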