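"""Transition structure, discounting, utility accrual and the two run modes."""

import numpy as np
import pytest

from cochlear_cea import (Arm, apply_override, run_cohort, run_microsim,
                          strategy_for)
from cochlear_cea.life_table import read_life_table
from cochlear_cea.markov_engine import (CycleContext, HealthState,
                                        discount_factor,
                                        transition_distribution,
                                        utility_increment)


def ctx_for(arm, age=10, t=5, replacements=0):
    return CycleContext(age=age, cycle_index=age, years_since_current_device=t,
                        replacements_done=replacements, arm=strategy_for(arm))


class TestTransitionDistribution:
    def test_death_is_absorbing(self, params, lt):
        dist = transition_distribution(HealthState.DEATH,
                                       ctx_for(Arm.BIMODAL), params, lt)
        assert sum(dist.values()) == 1.0
        assert all(s is HealthState.DEATH for (s, e) in dist)

    @pytest.mark.parametrize("state", [HealthState.DEV1, HealthState.DEV2,
                                       HealthState.DEV3])
    @pytest.mark.parametrize("arm", list(Arm))
    @pytest.mark.parametrize("age,t", [(1, 1), (3, 1), (3, 3), (10, 5),
                                       (40, 25), (84, 80)])
    def test_rows_sum_to_one(self, params, lt, state, arm, age, t):
        dist = transition_distribution(state, ctx_for(arm, age, t), params, lt)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_subsequent_year_complication_split(self, params, lt):
        """In steady state the 0.001/yr major-complication risk splits half
        wound (state unchanged) / half explantation (next device)."""
        dist = transition_distribution(HealthState.DEV1,
                                       ctx_for(Arm.BIMODAL, age=10, t=5),
                                       params, lt)
        qx = sum(p for (s, e), p in dist.items() if e.died)
        wound = sum(p for (s, e), p in dist.items()
                    if e.major_complication_wound)
        explant = sum(p for (s, e), p in dist.items()
                      if e.major_complication_explant)
        assert wound / (1 - qx) == pytest.approx(0.0005)
        assert explant / (1 - qx) == pytest.approx(0.0005)
        assert all(s is HealthState.DEV2 for (s, e) in dist
                   if e.major_complication_explant or e.internal_failure)

    def test_third_device_never_advances(self, params, lt):
        """Replacement cap: no transitions out of the third device except
        death (wound revisions do not change state)."""
        dist = transition_distribution(HealthState.DEV3,
                                       ctx_for(Arm.SIMULTANEOUS, age=30, t=12),
                                       params, lt)
        assert all(s in (HealthState.DEV3, HealthState.DEATH)
                   for (s, e) in dist)
        assert not any(e.internal_failure or e.major_complication_explant
                       for (s, e) in dist)

    def test_sequential_has_no_complications_before_second_implant(
            self, params, lt):
        dist = transition_distribution(HealthState.DEV1,
                                       ctx_for(Arm.SEQUENTIAL, age=2, t=2),
                                       params, lt)
        assert not any(e.major_complication_wound or e.major_complication_explant
                       for (s, e) in dist if dist[(s, e)] > 0)

    def test_clock_reset_restores_first_year_rates(self, params, lt):
        """The year after a re-implantation (t = 1) carries first-year
        complication rates again."""
        dist = transition_distribution(HealthState.DEV2,
                                       ctx_for(Arm.BIMODAL, age=30, t=1),
                                       params, lt)
        qx = sum(p for (s, e), p in dist.items() if e.died)
        wound = sum(p for (s, e), p in dist.items()
                    if e.major_complication_wound)
        assert wound / (1 - qx) == pytest.approx(
            params.clinical.p_wound_first_year)


class TestUtilityAndDiscounting:
    @pytest.mark.parametrize("age,arm,expected", [
        (60, Arm.SIMULTANEOUS, 0.227 + 0.0294),   # both increments
        (2, Arm.SEQUENTIAL, 0.212),               # second implant not yet placed
        (3, Arm.SEQUENTIAL, 0.212 + 0.027),       # active from implantation age
        (67, Arm.BIMODAL, 0.223),
        (82, Arm.SIMULTANEOUS, 0.167 + 0.0216),
    ])
    def test_utility_increment_printed_cells(self, params, age, arm, expected):
        assert utility_increment(age, strategy_for(arm),
                                 params.utilities) == pytest.approx(expected)

    def test_age_beyond_last_band_is_an_error(self, params):
        with pytest.raises(ValueError, match="outside"):
            utility_increment(85, strategy_for(Arm.BIMODAL), params.utilities)

    @pytest.mark.parametrize("rate,cycle,mid,expected", [
        (0.0, 7, False, 1.0),
        (0.03, 1, False, 1.0),                  # first-year costs undiscounted
        (0.03, 1, True, 1.03 ** -0.5),          # half-cycle correction
        (0.03, 10, False, 1.03 ** -9),
    ])
    def test_discount_factor(self, rate, cycle, mid, expected):
        assert discount_factor(rate, cycle, mid) == pytest.approx(expected,
                                                                  rel=1e-12)


class TestCohortMode:
    def test_zero_utility_increments_give_zero_qalys(self, params, lt):
        p = apply_override(params, "utilities.base_increment_bimodal", 0.0)
        p = apply_override(p, "utilities.base_increment_bilateral_extra", 0.0)
        trace = run_cohort(p, strategy_for(Arm.SIMULTANEOUS), lt)
        assert trace.totals.discounted_qaly == 0.0

    def test_discounting_lowers_qalys(self, params, lt):
        undiscounted = apply_override(params, "economic.discount_rate_annual",
                                      0.0)
        q0 = run_cohort(undiscounted, strategy_for(Arm.BIMODAL), lt)
        q3 = run_cohort(params, strategy_for(Arm.BIMODAL), lt)
        assert q0.totals.discounted_qaly > q3.totals.discounted_qaly

    def test_occupancy_is_a_distribution_every_cycle(self, params, lt):
        trace = run_cohort(params, strategy_for(Arm.SEQUENTIAL), lt)
        for rec in trace.cycles:
            occ = np.array(list(rec.occupancy.values()))
            assert np.all(occ >= -1e-15)
            assert occ.sum() == pytest.approx(1.0, abs=1e-9)

    def test_totals_equal_per_cycle_sums(self, params, lt):
        trace = run_cohort(params, strategy_for(Arm.SIMULTANEOUS), lt)
        assert trace.totals.discounted_cost == pytest.approx(
            sum(r.cost_accrued_discounted for r in trace.cycles), abs=1e-9)
        assert trace.totals.discounted_qaly == pytest.approx(
            sum(r.utility_accrued_discounted for r in trace.cycles), abs=1e-9)

    def test_uniformly_higher_mortality_lowers_qalys_and_costs(self, params,
                                                               lt):
        worse = read_life_table(
            "age,qx\n" + "\n".join(
                f"{a},{min(1.0, q * 3)}" for a, q in zip(lt.ages, lt.qx)))
        base = run_cohort(params, strategy_for(Arm.SIMULTANEOUS), lt).totals
        short = run_cohort(params, strategy_for(Arm.SIMULTANEOUS),
                           worse).totals
        assert short.discounted_qaly < base.discounted_qaly
        assert short.discounted_cost < base.discounted_cost

    def test_refuses_invalid_parameters(self, params, lt):
        bad = apply_override(params, "clinical.p_major_subsequent", 1.2)
        with pytest.raises(ValueError, match="invalid parameters"):
            run_cohort(bad, strategy_for(Arm.BIMODAL), lt)


class TestMicrosimMode:
    def test_same_seed_is_bit_identical(self, params, lt):
        a = run_microsim(params, strategy_for(Arm.SEQUENTIAL), lt, 2000, 7)
        b = run_microsim(params, strategy_for(Arm.SEQUENTIAL), lt, 2000, 7)
        assert a.discounted_cost == b.discounted_cost
        assert a.discounted_qaly == b.discounted_qaly

    def test_single_deterministic_individual_matches_closed_form(self, params):
        """With mortality, complications and failures all switched off, one
        simulated individual accrues exactly the deterministic discounted
        utility stream."""
        p = params
        for path in ("clinical.p_major_first_year", "clinical.p_major_subsequent",
                     "clinical.p_wound_first_year", "clinical.p_wound_subsequent",
                     "clinical.p_explant_first_year",
                     "clinical.p_explant_subsequent",
                     "reliability.slope_per_year"):
            p = apply_override(p, path, 0.0)
        p = apply_override(p, "reliability.intercept", 1.0)
        immortal = read_life_table(
            "age,qx\n" + "\n".join(f"{a},0" for a in range(0, 120)) + "\n120,1")
        strat = strategy_for(Arm.BIMODAL)
        res = run_microsim(p, strat, immortal, 1, 0)
        expected = sum(
            p.utilities.bimodal_increment(age) * 1.03 ** -(age - 0.5)
            for age in range(1, 85))
        assert res.discounted_qaly == pytest.approx(expected, rel=1e-12)
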