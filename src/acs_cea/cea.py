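"""Incremental cost-effectiveness comparison and cohort impact projection.

The comparison is always antenatal corticosteroids (ACS) versus usual care
(no ACS).  Incremental cost IC = C_acs - C_no_acs and incremental
effectiveness IE = Q_acs - Q_no_acs come from the decision-tree expectation;
ICER = IC / IE when IE is nonzero.  Classification against a
willingness-to-pay threshold uses the standard dominance definitions:
ACS is dominant when it is no costlier and strictly more effective (or
strictly cheaper and no less effective), dominated in the mirror case, and
otherwise judged by ICER <= WTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterSet, require_valid
from .tree import evaluate_strategy

CLASSIFICATIONS = (
    "acs_dominant",
    "acs_cost_effective",
    "acs_not_cost_effective",
    "acs_dominated",
)

COHORT_OUTCOMES = ("acute", "chronic_respiratory", "neurodev_delay", "death")


@dataclass(frozen=True)
class CEAResult:
    ga_week: int
    cost_no_acs: float
    cost_acs: float
    qaly_no_acs: float
    qaly_acs: float
    incremental_cost: float
    incremental_effect: float
    icer: float | None  # None when IE == 0
    classification: str


@dataclass(frozen=True)
class CohortImpact:
    outcome: str
    n_cohort: int
    cases_no_acs: int
    cases_acs: int
    cases_prevented: int
    cost_delta: float


def classify_strategy(ic: float, ie: float, wtp: float) -> str:
    """Dominance / cost-effectiveness classification of ACS vs usual care."""
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay threshold must be positive, got {wtp}")
    if ic == 0.0 and ie == 0.0:
        return "acs_cost_effective"  # indifference
    if (ic <= 0.0 and ie > 0.0) or (ic < 0.0 and ie >= 0.0):
        return "acs_dominant"
    if (ic >= 0.0 and ie < 0.0) or (ic > 0.0 and ie <= 0.0):
        return "acs_dominated"
    if ie > 0.0 and ic / ie <= wtp:
        return "acs_cost_effective"
    return "acs_not_cost_effective"


def compare(params: ParameterSet, validate: bool = True) -> CEAResult:
    """Evaluate both strategy arms and classify ACS at the configured WTP."""
    if validate:
        require_valid(params)
    no_acs = evaluate_strategy("no_acs", params, validate=False)
    acs = evaluate_strategy("acs", params, validate=False)
    ic = acs.expected_cost - no_acs.expected_cost
    ie = acs.expected_qaly - no_acs.expected_qaly
    icer = ic / ie if ie != 0.0 else None
    return CEAResult(
        ga_week=params.ga_week,
        cost_no_acs=no_acs.expected_cost,
        cost_acs=acs.expected_cost,
        qaly_no_acs=no_acs.expected_qaly,
        qaly_acs=acs.expected_qaly,
        incremental_cost=ic,
        incremental_effect=ie,
        icer=icer,
        classification=classify_strategy(ic, ie, params.settings.wtp),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_impact(params: ParameterSet, n_cohort: int, outcome: str) -> CohortImpact:
    """Project adverse-outcome counts for a hypothetical birth cohort.

    Per-arm cases are round(p * n); prevented cases are rounded from the
    unrounded probability difference times n (round half away from zero),
    so prevented may differ by one from the difference of the rounded
    per-arm counts.  cost_delta is the package's internally consistent
    figure: unrounded prevented cases times the outcome's unit cost, minus —
    for the acute outcome only — the cohort-wide incremental delivery cost
    of universal steroid administration.
    """
    if n_cohort <= 0:
        raise ValueError(f"n_cohort must be positive, got {n_cohort}")
    if outcome == "acute":
        p_no = params.acute.prob_no_acs.point
        p_acs = params.acute.prob_acs.point
        unit_cost = params.acute.cost.point
    elif outcome in COHORT_OUTCOMES:
        c = params.chronic_by_name(outcome)
        p_no, p_acs = c.prob_no_acs.point, c.prob_acs.point
        unit_cost = c.cost.point
    else:
        raise ValueError(f"unknown outcome {outcome!r}; valid: {COHORT_OUTCOMES}")
    prevented_exact = (p_no - p_acs) * n_cohort
    cost_delta = prevented_exact * unit_cost
    if outcome == "acute":
        cost_delta -= n_cohort * (
            params.delivery_cost_acs.point - params.delivery_cost_no_acs.point
        )
    return CohortImpact(
        outcome=outcome,
        n_cohort=n_cohort,
        cases_no_acs=_round_half_away(p_no * n_cohort),
        cases_acs=_round_half_away(p_acs * n_cohort),
        cases_prevented=_round_half_away(prevented_exact),
        cost_delta=cost_delta,
    )
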