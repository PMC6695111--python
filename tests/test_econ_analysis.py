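"""ICER/dominance logic, tornado DSA, PSA sampling and CEACs."""

import numpy as np
import pytest

from cochlear_cea import (Arm, apply_override, base_case, ceac, run_psa,
                          sample_psa_parameters, strategy_for)
from cochlear_cea.econ_analysis import (Dominance, PsaDraw, _beta_moments,
                                        _gamma_moments, compute_icer,
                                        default_dsa_plan, one_way_dsa)
from cochlear_cea.markov_engine import ArmResult


def result(cost, qaly, arm=Arm.BIMODAL):
    return ArmResult(discounted_cost=cost, discounted_qaly=qaly,
                     arm=strategy_for(arm))


class TestIcer:
    def test_table5_simultaneous_division(self):
        res = compute_icer(result(81260, 6.82),
                           result(81260 + 53451, 6.82 + 0.88))
        assert res.icer == pytest.approx(53451 / 0.88)
        assert res.icer == pytest.approx(60739.8, abs=0.1)
        assert res.dominance is Dominance.NONE

    def test_table5_sequential_division(self):
        res = compute_icer(result(81260, 6.82),
                           result(81260 + 67533, 6.82 + 0.83))
        assert res.icer == pytest.approx(67533 / 0.83)
        assert res.icer == pytest.approx(81365, abs=1)

    def test_cheaper_and_better_dominates(self):
        res = compute_icer(result(100, 1.0), result(90, 1.5))
        assert res.dominance is Dominance.INTERVENTION_DOMINANT
        assert res.icer is None

    def test_costlier_and_worse_is_dominated(self):
        res = compute_icer(result(100, 1.0), result(150, 0.5))
        assert res.dominance is Dominance.INTERVENTION_DOMINATED
        assert res.icer is None

    def test_zero_qaly_delta_is_undefined(self):
        res = compute_icer(result(100, 1.0), result(150, 1.0))
        assert res.icer is None
        assert res.dominance is Dominance.INTERVENTION_DOMINATED


class TestOneWayDsa:
    def test_degenerate_range_has_zero_width(self, params, lt):
        entries = one_way_dsa(
            params, [("costs.hearing_aid", 949.0, 949.0)],
            (strategy_for(Arm.BIMODAL), strategy_for(Arm.SIMULTANEOUS)), lt)
        assert entries[0].bar_width == 0.0

    def test_acquisition_cost_raises_icer_monotonically(self, params, lt):
        entries = one_way_dsa(
            params, [("costs.bilateral_acquisition_multiplier", 0.9, 1.1)],
            (strategy_for(Arm.BIMODAL), strategy_for(Arm.SIMULTANEOUS)), lt)
        base = base_case(params, lt)["simultaneous_vs_bimodal"].icer
        assert entries[0].icer_at_low < base < entries[0].icer_at_high

    def test_tornado_ordering_and_leading_bars(self, params, lt):
        """Utility gain and acquisition cost carry the widest bars, in that
        order, and entries come back sorted by impact."""
        entries = one_way_dsa(
            params, default_dsa_plan(params),
            (strategy_for(Arm.BIMODAL), strategy_for(Arm.SIMULTANEOUS)), lt)
        widths = [e.bar_width for e in entries]
        assert widths == sorted(widths, reverse=True)
        assert entries[0].parameter_path == \
            "utilities.base_increment_bilateral_extra"
        assert entries[1].parameter_path == \
            "costs.bilateral_acquisition_multiplier"


class TestPsaSampling:
    def test_moment_matching_closed_forms(self):
        k, theta = _gamma_moments(28216.0, 28216.0)
        assert (k, theta) == (pytest.approx(1.0), pytest.approx(28216.0))
        a, b = _beta_moments(0.03, 0.03)
        nu = 0.03 * 0.97 / 0.03 ** 2 - 1
        assert a == pytest.approx(0.03 * nu)
        assert b == pytest.approx(0.97 * nu)

    def test_infeasible_beta_sd_is_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="infeasible"):
            a, b = _beta_moments(0.7, 0.7)
        assert a > 0 and b > 0

    def test_cv_zero_returns_base_values(self, params):
        draws = sample_psa_parameters(params, np.random.default_rng(0), cv=0.0)
        assert draws["costs.ci_device"] == 28216.0
        assert draws["utilities.base_increment_bilateral_extra"] == 0.03

    def test_sampling_moments_match_targets(self, params):
        """Law-of-large-numbers check at CV = 1: the sampled device cost has
        mean within 3% and SD within 5% of the base value."""
        rng = np.random.default_rng(12345)
        vals = np.array([sample_psa_parameters(params, rng)["costs.ci_device"]
                         for _ in range(10_000)])
        assert vals.mean() == pytest.approx(28216.0, rel=0.03)
        assert vals.std(ddof=1) == pytest.approx(28216.0, rel=0.05)
        utils = np.array([
            sample_psa_parameters(params, np.random.default_rng(i))
            ["utilities.base_increment_bilateral_extra"] for i in range(2000)])
        assert np.all((utils > 0) & (utils < 1))


class TestRunPsa:
    def test_same_seed_reproduces_draws(self, params, lt):
        arms = [strategy_for(a) for a in Arm]
        d1 = run_psa(params, arms, 20, 99, lt)
        d2 = run_psa(params, arms, 20, 99, lt)
        for a, b in zip(d1, d2):
            assert a.sampled_parameters == b.sampled_parameters

    def test_cv_zero_single_draw_equals_base_case(self, params, lt):
        arms = [strategy_for(a) for a in Arm]
        draw = run_psa(params, arms, 1, 0, lt, cv=0.0)[0]
        det = base_case(params, lt)
        for arm in Arm:
            assert draw.arm_results[arm].discounted_qaly == pytest.approx(
                det["arms"][arm].discounted_qaly, rel=1e-9)
            assert draw.arm_results[arm].discounted_cost == pytest.approx(
                det["arms"][arm].discounted_cost, rel=1e-9)

    def test_loadings_evaluation_equals_direct_cohort_runs(self, params, lt):
        """Dual route: reweighting the cohort loadings must agree with
        applying the sampled overrides and re-running the cohort."""
        arms = [strategy_for(a) for a in Arm]
        fast = run_psa(params, arms, 3, 7, lt, method="loadings")
        slow = run_psa(params, arms, 3, 7, lt, method="direct")
        for f, s in zip(fast, slow):
            for arm in Arm:
                assert f.arm_results[arm].discounted_cost == pytest.approx(
                    s.arm_results[arm].discounted_cost, abs=1e-6)
                assert f.arm_results[arm].discounted_qaly == pytest.approx(
                    s.arm_results[arm].discounted_qaly, abs=1e-9)


class TestCeac:
    @staticmethod
    def synthetic_draws():
        """Three hand-made draws with a known optimum at each WTP."""
        draws = []
        for i, (cb, qb, cs, qs) in enumerate([
                (100, 1.0, 200, 2.0), (100, 1.0, 190, 2.0),
                (100, 1.0, 400, 1.5)]):
            draws.append(PsaDraw(i, {}, {
                Arm.BIMODAL: result(cb, qb),
                Arm.SIMULTANEOUS: result(cs, qs, Arm.SIMULTANEOUS)}))
        return draws

    def test_zero_wtp_prefers_cheapest(self):
        table = ceac(self.synthetic_draws(), [0.0])
        assert table.probabilities.loc[0.0, "bimodal"] == 1.0

    def test_rows_sum_to_one_and_probabilities_shift(self):
        table = ceac(self.synthetic_draws(), [0.0, 95.0, 150.0, 1000.0])
        sums = table.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        # at WTP 150 two of three draws favour the bilateral strategy
        assert table.probabilities.loc[150.0, "simultaneous"] == \
            pytest.approx(2 / 3)

    def test_crossing_interpolates_between_grid_points(self):
        table = ceac(self.synthetic_draws(), [0.0, 50.0, 120.0, 1000.0])
        cross = table.crossing(Arm.BIMODAL, Arm.SIMULTANEOUS)
        assert cross is not None
        assert 50.0 < cross <= 120.0
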