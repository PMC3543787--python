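"""Distribution fitting and the seeded second-order Monte Carlo analysis."""

import dataclasses
import math

import numpy as np
import pytest

from acs_cea.cea import compare
from acs_cea.parameters import Estimate
from acs_cea.psa import (
    ceac_curve,
    confidence_wtp_threshold,
    fit_beta_from_estimate,
    fit_normal_from_estimate,
    proportion_acceptable,
    psa_classifications,
    run_psa,
)


class TestBetaFit:
    def test_method_of_moments_example(self):
        # mean 0.07, sd (0.14-0.03)/3.92: alpha = m(m(1-m)/v - 1)
        spec = fit_beta_from_estimate(Estimate(0.07, 0.03, 0.14))
        assert spec.alpha == pytest.approx(5.72, rel=0.01)
        assert spec.beta == pytest.approx(75.9, rel=0.01)

    def test_analytic_mean_matches_point(self):
        for e in (Estimate(0.07, 0.03, 0.14), Estimate(0.0043656, 0.004012, 0.004692),
                  Estimate(0.5, 0.2, 0.8)):
            spec = fit_beta_from_estimate(e)
            assert spec.analytic_mean == pytest.approx(e.point, abs=1e-9)

    def test_symmetric_estimate_gives_equal_shapes(self):
        spec = fit_beta_from_estimate(Estimate(0.5, 0.3, 0.7))
        assert spec.alpha == pytest.approx(spec.beta, abs=1e-12)

    def test_infeasible_variance_shrunk_to_feasible(self):
        # huge range relative to the mean would imply v >= m(1-m)
        spec = fit_beta_from_estimate(Estimate(0.02, 0.0, 1.0))
        assert spec.alpha > 0 and spec.beta > 0
        implied_sd = math.sqrt(
            spec.alpha * spec.beta
            / ((spec.alpha + spec.beta) ** 2 * (spec.alpha + spec.beta + 1))
        )
        assert implied_sd < math.sqrt(0.02 * 0.98)

    def test_degenerate_point_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_from_estimate(Estimate(0.0, 0.0, 0.1))


class TestNormalFit:
    def test_utility_fit_example(self):
        spec = fit_normal_from_estimate(Estimate(0.87, 0.79, 0.93), "utility")
        assert spec.mean == 0.87
        assert spec.sd == pytest.approx((0.93 - 0.79) / 3.92)
        assert (spec.lower_bound, spec.upper_bound) == (0.0, 1.0)

    def test_cost_fit_truncated_at_zero(self):
        spec = fit_normal_from_estimate(Estimate(2505, 334, 50657), "cost")
        assert spec.lower_bound == 0.0 and spec.upper_bound == math.inf

    def test_zero_width_range_is_point_mass(self):
        spec = fit_normal_from_estimate(Estimate(0.5, 0.5, 0.5), "utility")
        assert spec.kind == "point"
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 0.5

    def test_sampling_mean_matches_point_under_mild_truncation(self):
        spec = fit_normal_from_estimate(Estimate(0.87, 0.79, 0.93), "utility")
        rng = np.random.default_rng(7)
        draws = np.array([spec.sample(rng) for _ in range(100_000)])
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.87) < 3 * se


def degenerate_copy(params):
    """All ranges collapsed to the point estimate (zero-variance PSA)."""

    def collapse(e):
        return Estimate(e.point, e.point, e.point)

    acute = dataclasses.replace(
        params.acute,
        prob_no_acs=collapse(params.acute.prob_no_acs),
        prob_acs=collapse(params.acute.prob_acs),
        utility=collapse(params.acute.utility),
        cost=collapse(params.acute.cost),
    )
    chronic = tuple(
        dataclasses.replace(
            c,
            prob_no_acs=collapse(c.prob_no_acs),
            prob_acs=collapse(c.prob_acs),
            utility=collapse(c.utility),
            cost=collapse(c.cost),
        )
        for c in params.chronic
    )
    return dataclasses.replace(
        params,
        acute=acute,
        chronic=chronic,
        delivery_cost_no_acs=collapse(params.delivery_cost_no_acs),
        delivery_cost_acs=collapse(params.delivery_cost_acs),
    )


class TestRunPsa:
    def test_same_seed_reproduces_bit_identical_draws(self, builtin34):
        a = run_psa(builtin34, 200, seed=42, scope="all")
        b = run_psa(builtin34, 200, seed=42, scope="all")
        assert np.array_equal(a.draws, b.draws)

    def test_different_seeds_differ(self, builtin34):
        a = run_psa(builtin34, 50, seed=1)
        b = run_psa(builtin34, 50, seed=2)
        assert not np.array_equal(a.draws, b.draws)

    @pytest.mark.parametrize("scope", ["acute_only", "chronic_only", "all"])
    def test_zero_variance_psa_equals_base_case(self, builtin34, scope):
        base = compare(builtin34)
        result = run_psa(degenerate_copy(builtin34), 10, seed=3, scope=scope)
        assert np.allclose(result.incremental_cost, base.incremental_cost)
        assert np.allclose(result.incremental_effect, base.incremental_effect)

    def test_scope_restriction_fixes_out_of_scope_values(self, builtin34):
        """Acute-only variation leaves both arms' chronic contribution at
        base case, so incremental effect varies far less than full scope."""
        acute = run_psa(builtin34, 300, seed=5, scope="acute_only")
        full = run_psa(builtin34, 300, seed=5, scope="all")
        assert acute.incremental_effect.std() < 0.1 * full.incremental_effect.std()

    def test_iterations_validated(self, builtin34):
        with pytest.raises(ValueError):
            run_psa(builtin34, 0, seed=1)


@pytest.fixture(scope="module")
def psa_result():
    from acs_cea.parameters import builtin_parameter_set

    return run_psa(builtin_parameter_set(34), 2_000, seed=11, scope="all")


class TestSummaries:

    def test_proportion_matches_per_iteration_recount(self, psa_result):
        wtp = 100_000.0
        prop = proportion_acceptable(psa_result, wtp)
        recount = sum(
            c in ("acs_dominant", "acs_cost_effective")
            for c in psa_classifications(psa_result, wtp)
        ) / psa_result.n_iterations
        assert prop == pytest.approx(recount, abs=1e-12)

    def test_ceac_nondecreasing_in_wtp(self, psa_result):
        curve = ceac_curve(psa_result, [0, 25_000, 50_000, 100_000, 500_000])
        props = [p for _, p in curve]
        assert props == sorted(props)

    def test_ceac_limits(self, psa_result):
        assert proportion_acceptable(psa_result, 1e12) >= proportion_acceptable(
            psa_result, 1.0
        )

    def test_confidence_threshold_consistent_with_curve(self, psa_result):
        for level in (0.5, 0.6):
            threshold = confidence_wtp_threshold(psa_result, level)
            if threshold is None:
                assert proportion_acceptable(psa_result, 1e15) < level
            else:
                assert proportion_acceptable(psa_result, threshold) >= level
                assert proportion_acceptable(psa_result, threshold * 0.999) < level

    def test_confidence_threshold_nonincreasing_in_level(self, psa_result):
        t40 = confidence_wtp_threshold(psa_result, 0.40)
        t60 = confidence_wtp_threshold(psa_result, 0.60)
        if t40 is not None and t60 is not None:
            assert t40 <= t60

    def test_zero_variance_threshold_is_base_icer(self, builtin34):
        base = compare(builtin34)
        result = run_psa(degenerate_copy(builtin34), 20, seed=9)
        assert confidence_wtp_threshold(result, 0.95) == pytest.approx(base.icer)

    def test_monte_carlo_error_scaling(self, builtin34):
        """Acceptable proportion at n=1,000 agrees with n=4,000 within
        4*sqrt(p(1-p)/1000)."""
        small = run_psa(builtin34, 1_000, seed=13, scope="all")
        large = run_psa(builtin34, 4_000, seed=17, scope="all")
        p_small = proportion_acceptable(small, 100_000)
        p_large = proportion_acceptable(large, 100_000)
        bound = 4 * math.sqrt(p_large * (1 - p_large) / 1_000)
        assert abs(p_small - p_large) < bound
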