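"""Decision-tree engine: discounting, path enumeration, QALY/cost accrual,
and oracle equivalence of the expectation with direct Monte Carlo sampling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acs_cea.parameters import Estimate
from acs_cea.sensitivity import set_point
from acs_cea.synthetic import SynthesisRegime, generate_parameter_set
from acs_cea.tree import (
    discount_weight,
    enumerate_paths,
    evaluate_strategy,
    path_cost,
    path_qaly,
)


def summation_discount_oracle(duration, rate):
    """Direct year-by-year summation, independent of the closed form."""
    total, t = 0.0, 0
    while duration > 0:
        total += min(duration, 1.0) * (1.0 + rate) ** (-t)
        duration -= 1.0
        t += 1
    return total


class TestDiscountWeight:
    @given(st.floats(min_value=0.0, max_value=120.0))
    @settings(deadline=None)
    def test_zero_rate_returns_duration(self, duration):
        assert discount_weight(duration, 0.0) == duration

    def test_year_zero_undiscounted(self):
        assert discount_weight(1.0, 0.03) == 1.0

    @pytest.mark.parametrize("duration", [0.5, 1.0, 2.25, 17.0, 78.2])
    @pytest.mark.parametrize("rate", [0.01, 0.03, 0.1])
    def test_matches_summation_oracle(self, duration, rate):
        assert discount_weight(duration, rate) == pytest.approx(
            summation_discount_oracle(duration, rate), rel=1e-12
        )

    def test_lifetime_at_three_percent(self):
        assert discount_weight(78.2, 0.03) == pytest.approx(
            summation_discount_oracle(78.2, 0.03)
        )

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            discount_weight(-1.0, 0.03)


class TestEnumeration:
    def test_ten_paths_summing_to_one(self, builtin_each_week):
        for strategy in ("no_acs", "acs"):
            paths = enumerate_paths(strategy, builtin_each_week)
            assert len(paths) == 10
            assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-12)

    def test_death_paths_never_carry_crd(self, builtin34):
        for p in enumerate_paths("acs", builtin34):
            if p.long_term == "death":
                assert not p.has_crd

    def test_example_path_probability_is_branch_product(self, builtin34):
        # no-ACS, acute disease, healthy survivor, no chronic disease
        expected = 0.1312 * (1 - 0.00642 - 0.00246) * (1 - 0.07)
        (path,) = [
            p
            for p in enumerate_paths("no_acs", builtin34)
            if p.has_ard and p.long_term == "healthy" and not p.has_crd
        ]
        assert path.probability == pytest.approx(expected, rel=1e-12)

    def test_probabilities_sum_to_one_on_synthetic_sets(self):
        for seed in range(100):
            params = generate_parameter_set(SynthesisRegime(seed=seed))
            for strategy in ("no_acs", "acs"):
                total = sum(
                    p.probability for p in enumerate_paths(strategy, params)
                )
                assert total == pytest.approx(1.0, abs=1e-12)


def undiscounted(params):
    return dataclasses.replace(
        params,
        settings=dataclasses.replace(
            params.settings, discount_rate=0.0, discount_qalys=False
        ),
    )


class TestQalyAccrual:
    def test_perfect_health_undiscounted(self, builtin34):
        p = undiscounted(builtin34)
        assert path_qaly(False, "healthy", False, p) == pytest.approx(78.2)

    def test_delay_with_chronic_disease_closed_form(self, builtin34):
        p = undiscounted(builtin34)
        # 0.76 * 0.88 over 17 years, minus the acute-window substitution of
        # the healthy utility (1.0) for 6/52 years
        acute = 6.0 / 52.0
        expected = 1.0 * acute + 0.76 * 0.88 * (17.0 - acute)
        assert path_qaly(False, "delay", True, p) == pytest.approx(expected)

    def test_acute_disease_window_substitutes_utility(self, builtin34):
        p = undiscounted(builtin34)
        acute = 6.0 / 52.0
        expected = 0.87 * acute + 1.0 * (78.2 - acute)
        assert path_qaly(True, "healthy", False, p) == pytest.approx(expected)

    def test_qaly_discounting_can_be_disabled(self, builtin34):
        discounted = path_qaly(False, "healthy", False, builtin34)
        plain = path_qaly(False, "healthy", False, undiscounted(builtin34))
        assert discounted < plain


class TestCostAccrual:
    def test_fully_healthy_path_is_delivery_cost_only(self, builtin34):
        assert path_cost(False, "healthy", False, "no_acs", builtin34) == 8449.0

    def test_acute_path_adds_one_time_cost(self, builtin34):
        p = undiscounted(builtin34)
        assert path_cost(True, "healthy", False, "acs", p) == 16277.0 + 2505.0

    def test_chronic_respiratory_lifetime_cost_undiscounted(self, builtin34):
        p = undiscounted(builtin34)
        cost = path_cost(False, "healthy", True, "no_acs", p)
        assert cost == pytest.approx(8449.0 + 56641.0)

    def test_chronic_cost_discounting_reduces_total(self, builtin34):
        assert path_cost(False, "healthy", True, "no_acs", builtin34) < 8449 + 56641


class TestExpectation:
    def test_zero_adverse_probabilities_leave_only_delivery_delta(self, builtin34):
        zero = Estimate(0.0, 0.0, 0.0)
        acute = dataclasses.replace(
            builtin34.acute, prob_no_acs=zero, prob_acs=zero
        )
        chronic = tuple(
            dataclasses.replace(c, prob_no_acs=zero, prob_acs=zero)
            for c in builtin34.chronic
        )
        p = dataclasses.replace(builtin34, acute=acute, chronic=chronic)
        no_acs = evaluate_strategy("no_acs", p)
        acs = evaluate_strategy("acs", p)
        assert acs.expected_qaly == pytest.approx(no_acs.expected_qaly, rel=1e-12)
        assert acs.expected_cost - no_acs.expected_cost == pytest.approx(
            16277.0 - 8449.0
        )

    def test_expectation_matches_monte_carlo_path_draws(self, builtin34):
        """Enumeration equals the mean of 10^6 sampled paths within 3 SE."""
        result = evaluate_strategy("no_acs", builtin34)
        probs = np.array([p.probability for p in result.paths])
        qalys = np.array([p.qaly for p in result.paths])
        costs = np.array([p.cost for p in result.paths])
        rng = np.random.default_rng(20260924)
        n = 1_000_000
        idx = rng.choice(len(probs), size=n, p=probs)
        for values, expected in ((qalys, result.expected_qaly),
                                 (costs, result.expected_cost)):
            sample = values[idx]
            se = sample.std(ddof=1) / np.sqrt(n)
            assert abs(sample.mean() - expected) < 3 * se

    def test_increasing_adverse_probability_never_raises_qaly(self, builtin34):
        for pid in (
            "acute.prob_no_acs",
            "chronic.chronic_respiratory.prob_no_acs",
            "chronic.death.prob_no_acs",
            "chronic.neurodev_delay.prob_no_acs",
        ):
            qalys = [
                evaluate_strategy(
                    "no_acs", set_point(builtin34, pid, v), validate=False
                ).expected_qaly
                for v in (0.01, 0.05, 0.2)
            ]
            assert qalys[0] > qalys[1] > qalys[2]

    def test_expected_qaly_bounded_by_perfect_health(self, builtin_each_week):
        p = undiscounted(builtin_each_week)
        for strategy in ("no_acs", "acs"):
            assert evaluate_strategy(strategy, p).expected_qaly <= 78.2

    def test_unknown_strategy_rejected(self, builtin34):
        with pytest.raises(ValueError, match="no_acs"):
            enumerate_paths("placebo", builtin34)
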