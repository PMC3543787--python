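"""Second-order Monte Carlo probabilistic sensitivity analysis (PSA).

Each uncertain input is given a parametric distribution derived from its
point estimate and plausible range, with the range read as a 95% interval
(sd = range / 3.92): beta distributions for probabilities (fitted by the
method of moments) and normal distributions for utilities and costs,
truncated to [0, 1] and [0, inf) respectively.  Each iteration redraws every
in-scope input, rebuilds the parameter set, and re-evaluates both strategy
arms through the decision tree.

Randomness is reproducible: a master seed spawns one substream per
iteration, and every input is drawn in a fixed canonical order whether or
not it is in scope, so restricting the scope (e.g. varying only the
acute-disease inputs) does not shift the draws of the remaining variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cea import classify_strategy
from .parameters import Estimate, ParameterSet, _iter_estimates, require_valid
from .tree import evaluate_strategy

RANGE_TO_SD = 3.92  # plausible range read as a central 95% interval

SCOPES = ("acute_only", "chronic_only", "all")

REJECTION_CAP = 10_000


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one input."""

    kind: str  # beta | normal_truncated | point
    alpha: float = math.nan
    beta: float = math.nan
    mean: float = math.nan
    sd: float = math.nan
    lower_bound: float = math.nan
    upper_bound: float = math.nan
    value: float = math.nan  # point mass

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.value
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta))
        if self.kind == "normal_truncated":
            if self.sd == 0.0:
                return self.mean
            for _ in range(REJECTION_CAP):
                x = rng.normal(self.mean, self.sd)
                if self.lower_bound <= x <= self.upper_bound:
                    return float(x)
            raise RuntimeError(
                f"truncated-normal sampling failed: mean {self.mean}, sd {self.sd} "
                f"incompatible with bounds [{self.lower_bound}, {self.upper_bound}]"
            )
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def analytic_mean(self) -> float:
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta)
        if self.kind == "point":
            return self.value
        return self.mean  # untruncated mean; truncation at [0,1]/[0,inf) is mild


@dataclass(frozen=True)
class PSAResult:
    n_iterations: int
    seed: int
    varied_scope: str
    # columns: cost_no_acs, qaly_no_acs, cost_acs, qaly_acs
    draws: np.ndarray

    @property
    def incremental_cost(self) -> np.ndarray:
        return self.draws[:, 2] - self.draws[:, 0]

    @property
    def incremental_effect(self) -> np.ndarray:
        return self.draws[:, 3] - self.draws[:, 1]


def fit_beta_from_estimate(e: Estimate) -> DistributionSpec:
    """Method-of-moments beta with mean e.point and sd = range/3.92.

    If the implied variance is infeasible (v >= m(1-m)) the sd is shrunk to
    0.95 of the feasible maximum.
    """
    m = e.point
    if not 0.0 < m < 1.0:
        raise ValueError(
            f"beta fit requires 0 < point < 1, got {m} (degenerate probability)"
        )
    if not e.low < e.high:
        raise ValueError(f"beta fit requires low < high, got ({e.low}, {e.high})")
    sd = (e.high - e.low) / RANGE_TO_SD
    sd_max = math.sqrt(m * (1.0 - m))
    if sd >= sd_max:
        sd = 0.95 * sd_max
    v = sd * sd
    k = m * (1.0 - m) / v - 1.0
    return DistributionSpec(kind="beta", alpha=m * k, beta=(1.0 - m) * k)


def fit_normal_from_estimate(e: Estimate, domain: str) -> DistributionSpec:
    """Truncated normal with mean e.point and sd = range/3.92.

    Utilities are truncated to [0, 1], costs to [0, inf).  A zero-width
    range yields a point mass at the point estimate.
    """
    if domain == "utility":
        lower, upper = 0.0, 1.0
    elif domain == "cost":
        lower, upper = 0.0, math.inf
    else:
        raise ValueError(f"unknown domain {domain!r}; expected utility or cost")
    sd = (e.high - e.low) / RANGE_TO_SD
    if sd == 0.0:
        return DistributionSpec(kind="point", value=e.point)
    return DistributionSpec(
        kind="normal_truncated", mean=e.point, sd=sd,
        lower_bound=lower, upper_bound=upper,
    )


def fit_distribution(e: Estimate, domain: str) -> DistributionSpec:
    """Distribution for one input by semantic domain; degenerate -> point mass."""
    if e.is_degenerate:
        return DistributionSpec(kind="point", value=e.point)
    if domain == "probability":
        return fit_beta_from_estimate(e)
    return fit_normal_from_estimate(e, domain)


def _scope_predicate(scope: str):
    if scope == "acute_only":
        return lambda pid: pid.startswith("acute.")
    if scope == "chronic_only":
        return lambda pid: pid.startswith("chronic.")
    if scope == "all":
        return lambda pid: True
    raise ValueError(f"unknown scope {scope!r}; valid: {SCOPES}")


def _override_estimate(est: Estimate, value: float | None) -> Estimate:
    if value is None:
        return est
    return Estimate(
        point=value, low=min(est.low, value), high=max(est.high, value)
    )


def _rebuild(params: ParameterSet, points: dict[str, float]) -> ParameterSet:
    """ParameterSet with point values overridden from the draw mapping."""
    acute = replace(
        params.acute,
        prob_no_acs=_override_estimate(
            params.acute.prob_no_acs, points.get("acute.prob_no_acs")
        ),
        prob_acs=_override_estimate(
            params.acute.prob_acs, points.get("acute.prob_acs")
        ),
        utility=_override_estimate(params.acute.utility, points.get("acute.utility")),
        cost=_override_estimate(params.acute.cost, points.get("acute.cost")),
    )
    chronic = tuple(
        replace(
            c,
            prob_no_acs=_override_estimate(
                c.prob_no_acs, points.get(f"chronic.{c.name}.prob_no_acs")
            ),
            prob_acs=_override_estimate(
                c.prob_acs, points.get(f"chronic.{c.name}.prob_acs")
            ),
            utility=_override_estimate(
                c.utility, points.get(f"chronic.{c.name}.utility")
            ),
            cost=_override_estimate(c.cost, points.get(f"chronic.{c.name}.cost")),
        )
        for c in params.chronic
    )
    return replace(
        params,
        acute=acute,
        chronic=chronic,
        delivery_cost_no_acs=_override_estimate(
            params.delivery_cost_no_acs, points.get("delivery_cost_no_acs")
        ),
        delivery_cost_acs=_override_estimate(
            params.delivery_cost_acs, points.get("delivery_cost_acs")
        ),
    )


def run_psa(
    params: ParameterSet,
    n_iterations: int,
    seed: int,
    scope: str = "all",
) -> PSAResult:
    """Seeded second-order Monte Carlo over the parameter distributions.

    Structural coherence (death + delay probabilities admitting a healthy
    remainder in each arm) is enforced by rejection-resampling the offending
    variables, capped at 10,000 attempts per iteration.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    require_valid(params)
    in_scope = _scope_predicate(scope)
    specs = [
        (pid, fit_distribution(est, domain))
        for pid, est, domain in _iter_estimates(params)
    ]
    base_points = {pid: est.point for pid, est, _ in _iter_estimates(params)}

    draws = np.empty((n_iterations, 4))
    for i in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        points: dict[str, float] = {}
        for pid, spec in specs:
            value = spec.sample(rng)  # always drawn, applied only in scope
            if in_scope(pid):
                points[pid] = value
        for arm in ("prob_no_acs", "prob_acs"):
            death_id, delay_id = f"chronic.death.{arm}", f"chronic.neurodev_delay.{arm}"
            attempts = 0
            while (
                points.get(death_id, base_points[death_id])
                + points.get(delay_id, base_points[delay_id])
                > 1.0
            ):
                attempts += 1
                if attempts > REJECTION_CAP:
                    raise RuntimeError(
                        f"rejection cap exceeded resampling {death_id}/{delay_id}"
                    )
                for pid, spec in specs:
                    if pid in (death_id, delay_id) and in_scope(pid):
                        points[pid] = spec.sample(rng)
        sampled = _rebuild(params, points)
        no_acs = evaluate_strategy("no_acs", sampled, validate=False)
        acs = evaluate_strategy("acs", sampled, validate=False)
        draws[i] = (
            no_acs.expected_cost,
            no_acs.expected_qaly,
            acs.expected_cost,
            acs.expected_qaly,
        )
    return PSAResult(
        n_iterations=n_iterations, seed=seed, varied_scope=scope, draws=draws
    )


def _acceptable_mask(result: PSAResult, wtp: float) -> np.ndarray:
    ic = result.incremental_cost
    ie = result.incremental_effect
    dominant = ((ic <= 0) & (ie > 0)) | ((ic < 0) & (ie >= 0))
    indifferent = (ic == 0) & (ie == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        within_wtp = (ie > 0) & (ic / ie <= wtp)
    return dominant | indifferent | within_wtp


def proportion_acceptable(result: PSAResult, wtp: float) -> float:
    """Fraction of iterations where ACS is dominant or has ICER <= wtp."""
    return float(_acceptable_mask(result, wtp).mean())


def ceac_curve(result: PSAResult, wtp_grid) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be nonempty")
    return [(float(w), proportion_acceptable(result, w)) for w in grid]


def confidence_wtp_threshold(result: PSAResult, level: float) -> float | None:
    """Smallest WTP at which the acceptable proportion reaches ``level``.

    Computed exactly from the per-iteration critical WTP values (the
    limiting refinement of a WTP grid): iterations where ACS dominates are
    acceptable at any threshold; iterations with positive incremental cost
    and effect become acceptable once wtp >= their ICER; all others never
    do.  Returns None when the proportion never reaches ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ic = result.incremental_cost
    ie = result.incremental_effect
    n = result.n_iterations
    always = int((((ic <= 0) & (ie > 0)) | ((ic < 0) & (ie >= 0))
                  | ((ic == 0) & (ie == 0))).sum())
    eventually = (ie > 0) & (ic > 0)
    k = math.ceil(level * n) - always
    if k <= 0:
        return 0.0
    icers = np.sort(ic[eventually] / ie[eventually])
    if k > icers.size:
        return None
    return float(icers[k - 1])


def psa_classifications(result: PSAResult, wtp: float) -> list[str]:
    """Per-iteration classification (independent scalar path, for checks)."""
    return [
        classify_strategy(float(ic), float(ie), wtp)
        for ic, ie in zip(result.incremental_cost, result.incremental_effect)
    ]
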