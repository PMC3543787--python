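"""Decision-tree evaluation: path enumeration, QALY and cost accrual.

Each strategy (give or withhold antenatal corticosteroids) leads to ten
terminal paths: acute respiratory disease (yes/no) crossed with the long-term
state (childhood death, neurodevelopmental delay or health), with chronic
respiratory disease (yes/no) branching only for survivors.  The three
branch families are treated as independent, with the chronic-respiratory
branch conditioned on survival.

QALYs substitute the acute-disease utility during the latency-to-term window
(duration_weeks / 52 years, within year 0) and apply the long-term state
utility — a product of the applicable state utilities — for the remainder of
the state duration.  Future QALYs and costs are discounted at the annual
rate in the economic settings, with year 0 undiscounted and the final
fractional year prorated linearly.  Delivery, acute-disease and death costs
are one-time year-0 expenses; chronic-respiratory and delay lifetime costs
are spread uniformly over the state duration and accrue only over years the
individual is alive.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .parameters import ParameterSet, require_valid

STRATEGIES = ("no_acs", "acs")

LONG_TERM_STATES = ("healthy", "delay", "death")

PROB_TOL = 1e-12


@dataclass(frozen=True)
class OutcomePath:
    """One terminal branch of the decision tree."""

    has_ard: bool
    long_term: str  # healthy | delay | death
    has_crd: bool  # always False on death paths
    probability: float
    qaly: float
    cost: float


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    expected_cost: float
    expected_qaly: float
    paths: tuple[OutcomePath, ...]


def _check_strategy(strategy: str) -> str:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {STRATEGIES}")
    return strategy


@lru_cache(maxsize=4096)
def discount_weight(duration_years: float, rate: float) -> float:
    """Discounted sum of one unit accrued per year over ``duration_years``.

    Year 0 is undiscounted; year t contributes (1+rate)^-t; the final
    fractional year is prorated linearly.  At rate 0 this is the duration
    itself.
    """
    if duration_years < 0:
        raise ValueError(f"duration must be nonnegative, got {duration_years}")
    if rate == 0.0:
        return duration_years
    n_full = int(duration_years)
    frac = duration_years - n_full
    v = 1.0 / (1.0 + rate)
    total = (1.0 - v**n_full) / (1.0 - v)
    if frac > 0.0:
        total += frac * v**n_full
    return total


def _arm_prob(est_no, est_acs, strategy: str) -> float:
    return est_acs.point if strategy == "acs" else est_no.point


def _path_structures():
    structures = []
    for has_ard in (False, True):
        structures.append((has_ard, "death", False))
        for long_term in ("delay", "healthy"):
            for has_crd in (False, True):
                structures.append((has_ard, long_term, has_crd))
    return structures


_STRUCTURES = tuple(_path_structures())


def path_probability(
    has_ard: bool, long_term: str, has_crd: bool, strategy: str, params: ParameterSet
) -> float:
    """Joint probability of one terminal path under the given strategy arm."""
    acute = params.acute
    p_ard = _arm_prob(acute.prob_no_acs, acute.prob_acs, strategy)
    p = p_ard if has_ard else 1.0 - p_ard

    death = params.death
    delay = params.neurodev_delay
    p_death = _arm_prob(death.prob_no_acs, death.prob_acs, strategy)
    p_delay = _arm_prob(delay.prob_no_acs, delay.prob_acs, strategy)
    if long_term == "death":
        return p * p_death
    p_long = p_delay if long_term == "delay" else 1.0 - p_death - p_delay
    crd = params.chronic_respiratory
    p_crd = _arm_prob(crd.prob_no_acs, crd.prob_acs, strategy)
    p_crd_branch = p_crd if has_crd else 1.0 - p_crd
    return p * p_long * p_crd_branch


def path_qaly(
    has_ard: bool, long_term: str, has_crd: bool, params: ParameterSet
) -> float:
    """Discounted QALYs accrued along one path.

    acute window (year 0): U_acute * duration_weeks/52, with U_acute the
    acute-disease utility when the path has acute disease, else the healthy
    utility.  Remainder: U_long * discount_weight(T_long - acute window),
    with U_long the product of the applicable long-term state utilities and
    T_long the duration of the long-term state (no accrual afterward).
    """
    s = params.settings
    rate = s.qaly_rate
    acute_years = params.acute.duration_weeks / 52.0
    u_acute = params.acute.utility.point if has_ard else s.healthy_utility

    if long_term == "death":
        u_long = params.death.utility.point
        t_long = params.death.duration_years
    elif long_term == "delay":
        u_long = params.neurodev_delay.utility.point
        t_long = params.neurodev_delay.duration_years
    else:
        u_long = s.healthy_utility
        t_long = s.life_expectancy_years
    if has_crd:
        u_long *= params.chronic_respiratory.utility.point
    return u_acute * acute_years + u_long * discount_weight(
        max(t_long - acute_years, 0.0), rate
    )


def path_cost(
    has_ard: bool, long_term: str, has_crd: bool, strategy: str, params: ParameterSet
) -> float:
    """Discounted cost accrued along one path for the given strategy."""
    rate = params.settings.discount_rate
    cost = (
        params.delivery_cost_acs.point
        if strategy == "acs"
        else params.delivery_cost_no_acs.point
    )
    if has_ard:
        cost += params.acute.cost.point
    if long_term == "death":
        cost += params.death.cost.point
        return cost
    years_alive = (
        params.neurodev_delay.duration_years
        if long_term == "delay"
        else params.settings.life_expectancy_years
    )
    if long_term == "delay":
        delay = params.neurodev_delay
        cost += (delay.cost.point / delay.duration_years) * discount_weight(
            delay.duration_years, rate
        )
    if has_crd:
        crd = params.chronic_respiratory
        cost += (crd.cost.point / crd.duration_years) * discount_weight(
            min(crd.duration_years, years_alive), rate
        )
    return cost


def enumerate_paths(strategy: str, params: ParameterSet) -> list[OutcomePath]:
    """All ten terminal paths with probability, discounted QALYs and cost."""
    _check_strategy(strategy)
    paths = [
        OutcomePath(
            has_ard=has_ard,
            long_term=long_term,
            has_crd=has_crd,
            probability=path_probability(has_ard, long_term, has_crd, strategy, params),
            qaly=path_qaly(has_ard, long_term, has_crd, params),
            cost=path_cost(has_ard, long_term, has_crd, strategy, params),
        )
        for has_ard, long_term, has_crd in _STRUCTURES
    ]
    total = sum(p.probability for p in paths)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"path probabilities sum to {total}, expected 1")
    return paths


def evaluate_strategy(
    strategy: str, params: ParameterSet, validate: bool = True
) -> StrategyResult:
    """Expected discounted cost and QALYs for one strategy arm."""
    if validate:
        require_valid(params)
    paths = enumerate_paths(strategy, params)
    expected_cost = sum(p.probability * p.cost for p in paths)
    expected_qaly = sum(p.probability * p.qaly for p in paths)
    return StrategyResult(
        strategy=strategy,
        expected_cost=expected_cost,
        expected_qaly=expected_qaly,
        paths=tuple(paths),
    )
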