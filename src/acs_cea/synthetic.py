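"""Synthetic parameter sets for property testing.

Generates random, always-valid ParameterSets with the same statistical
structure as the published tables — bounded per-arm probability estimates
with plausible ranges, utilities in [0, 1], nonnegative costs, and a
controllable treatment-effect direction — so every pipeline stage can be
exercised without the published values.  Also provides a closed-form
known-answer fixture for oracle tests against the tree expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    AcuteDiseaseParams,
    ChronicOutcomeParams,
    EconomicSettings,
    Estimate,
    ParameterSet,
    require_valid,
)
from .tree import discount_weight

# Probabilities are capped so death + delay always admits a healthy
# remainder without rejection sampling.
_PROB_CAPS = {"acute": 0.5, "chronic_respiratory": 0.5,
              "neurodev_delay": 0.25, "death": 0.25}

_ACUTE_WEEKS = {34: 6.0, 35: 5.0, 36: 4.0}


@dataclass(frozen=True)
class SynthesisRegime:
    seed: int
    effect_direction: str = "acs_better"  # acs_better | acs_worse | null
    magnitude: float = 0.3  # relative risk reduction (or increase) scale
    cost_premium: float = 5_000.0  # ACS delivery-cost increment

    def __post_init__(self):
        if self.effect_direction not in ("acs_better", "acs_worse", "null"):
            raise ValueError(
                f"unknown effect_direction {self.effect_direction!r}"
            )
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError(f"magnitude must be in [0, 1], got {self.magnitude}")
        if self.cost_premium < 0:
            raise ValueError(f"cost_premium must be >= 0, got {self.cost_premium}")


def _prob_estimate(rng: np.random.Generator, point: float, cap: float) -> Estimate:
    low = point * (1.0 - 0.5 * rng.uniform(0.2, 0.9))
    high = point + (cap - point) * rng.uniform(0.1, 0.5)
    return Estimate(point=point, low=low, high=min(high, cap))


def _acs_prob(p_no: float, regime: SynthesisRegime, cap: float) -> float:
    if regime.effect_direction == "null":
        return p_no
    if regime.effect_direction == "acs_better":
        return p_no * (1.0 - regime.magnitude)
    return p_no + regime.magnitude * (cap - p_no)  # acs_worse


def _utility_estimate(rng: np.random.Generator) -> Estimate:
    point = rng.uniform(0.3, 0.95)
    return Estimate(
        point=point,
        low=point * rng.uniform(0.7, 1.0),
        high=point + (1.0 - point) * rng.uniform(0.1, 0.9),
    )


def _cost_estimate(rng: np.random.Generator, lo: float, hi: float) -> Estimate:
    point = rng.uniform(lo, hi)
    return Estimate(point=point, low=point * rng.uniform(0.3, 0.9),
                    high=point * rng.uniform(1.1, 2.5))


def generate_parameter_set(regime: SynthesisRegime) -> ParameterSet:
    """Deterministic-per-seed random ParameterSet honouring all invariants."""
    rng = np.random.default_rng(regime.seed)
    ga_week = int(rng.choice((34, 35, 36)))

    def arm_pair(name: str) -> tuple[Estimate, Estimate]:
        cap = _PROB_CAPS[name]
        p_no = rng.uniform(0.01, cap * 0.9)
        p_acs = _acs_prob(p_no, regime, cap)
        return _prob_estimate(rng, p_no, cap), _prob_estimate(rng, p_acs, cap)

    acute_no, acute_acs = arm_pair("acute")
    acute = AcuteDiseaseParams(
        prob_no_acs=acute_no,
        prob_acs=acute_acs,
        utility=_utility_estimate(rng),
        duration_weeks=_ACUTE_WEEKS[ga_week],
        cost=_cost_estimate(rng, 500.0, 30_000.0),
    )
    chronic = []
    for name, duration, timing, cost_hi in (
        ("chronic_respiratory", 78.2, "spread_over_duration", 100_000.0),
        ("neurodev_delay", 17.0, "spread_over_duration", 400_000.0),
        ("death", 78.2, "one_time_year0", 100_000.0),
    ):
        p_no, p_acs = arm_pair(name)
        chronic.append(
            ChronicOutcomeParams(
                name=name,
                prob_no_acs=p_no,
                prob_acs=p_acs,
                utility=_utility_estimate(rng),
                duration_years=duration,
                cost=_cost_estimate(rng, 1_000.0, cost_hi),
                cost_timing=timing,
            )
        )
    delivery_no = _cost_estimate(rng, 3_000.0, 12_000.0)
    acs_point = delivery_no.point + regime.cost_premium
    delivery_acs = Estimate(
        point=acs_point, low=acs_point * 0.8, high=acs_point * 1.2
    )
    params = ParameterSet(
        ga_week=ga_week,
        acute=acute,
        chronic=tuple(chronic),
        delivery_cost_no_acs=delivery_no,
        delivery_cost_acs=delivery_acs,
        settings=EconomicSettings(),
    )
    return require_valid(params)


@dataclass(frozen=True)
class KnownAnswer:
    """A parameter set whose incremental cost/effect have closed forms."""

    params: ParameterSet
    expected_ic: float
    expected_ie: float


def known_answer_fixture(
    ic_target: float = 1_000.0,
    ie_sign: str = "positive",
    discount_rate: float = 0.0,
    crd_prob: float = 0.05,
    crd_utility: float = 0.88,
) -> KnownAnswer:
    """Single-risk fixture with analytic incremental cost and effect.

    All adverse probabilities are zero except a chronic-respiratory risk
    ``crd_prob`` placed in the no-ACS arm (ie_sign='positive'), the ACS arm
    ('negative'), or neither ('zero').  The chronic-respiratory cost is zero
    so IC equals the delivery-cost difference exactly; the closed form for
    the effect is IE = +/- p * (1 - U_crd) * discount_weight(T, rate).
    """
    if ie_sign not in ("positive", "negative", "zero"):
        raise ValueError(f"unknown ie_sign {ie_sign!r}")
    zero = Estimate(0.0, 0.0, 0.0)
    life = 78.2
    p = Estimate(crd_prob, crd_prob, crd_prob)
    crd_no = p if ie_sign == "positive" else zero
    crd_acs = p if ie_sign == "negative" else zero
    settings = EconomicSettings(discount_rate=discount_rate)
    params = ParameterSet(
        ga_week=34,
        acute=AcuteDiseaseParams(
            prob_no_acs=zero, prob_acs=zero,
            utility=Estimate(0.87, 0.87, 0.87),
            duration_weeks=6.0, cost=Estimate(2505.0, 2505.0, 2505.0),
        ),
        chronic=(
            ChronicOutcomeParams(
                name="chronic_respiratory", prob_no_acs=crd_no, prob_acs=crd_acs,
                utility=Estimate(crd_utility, crd_utility, crd_utility),
                duration_years=life, cost=zero,
                cost_timing="spread_over_duration",
            ),
            ChronicOutcomeParams(
                name="neurodev_delay", prob_no_acs=zero, prob_acs=zero,
                utility=Estimate(0.76, 0.76, 0.76), duration_years=17.0,
                cost=zero, cost_timing="spread_over_duration",
            ),
            ChronicOutcomeParams(
                name="death", prob_no_acs=zero, prob_acs=zero,
                utility=Estimate(0.01, 0.01, 0.01), duration_years=life,
                cost=zero, cost_timing="one_time_year0",
            ),
        ),
        delivery_cost_no_acs=Estimate(8_000.0, 8_000.0, 8_000.0),
        delivery_cost_acs=Estimate(
            8_000.0 + ic_target, 8_000.0 + ic_target, 8_000.0 + ic_target
        ),
        settings=settings,
    )
    require_valid(params)
    acute_years = 6.0 / 52.0
    qaly_loss = crd_prob * (1.0 - crd_utility) * discount_weight(
        life - acute_years, settings.qaly_rate
    )
    if ie_sign == "positive":
        expected_ie = qaly_loss  # risk removed by ACS
    elif ie_sign == "negative":
        expected_ie = -qaly_loss
    else:
        expected_ie = 0.0
    return KnownAnswer(params=params, expected_ic=ic_target, expected_ie=expected_ie)
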