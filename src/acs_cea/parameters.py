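"""Model parameters for the late-preterm antenatal-corticosteroid decision model.

Every model input is an :class:`Estimate` — a point value with a plausible
(low, high) range.  A :class:`ParameterSet` bundles the full set of inputs for
one gestational-age week: per-strategy probabilities of the acute outcome
(neonatal respiratory distress), the three long-term outcomes (chronic
respiratory disease, neurodevelopmental delay, childhood death), the health
state utilities and durations, one-time and lifetime costs, and the economic
settings (discount rate, willingness-to-pay threshold).

Built-in parameter sets encode the published estimates for deliveries at 34,
35 and 36 weeks gestation (costs in 2011 US dollars).  User-supplied YAML or
JSON files with the same schema are supported via :func:`load_parameter_set`
and :func:`save_parameter_set`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

SCHEMA_VERSION = 1

GA_WEEKS = (34, 35, 36)

CHRONIC_NAMES = ("chronic_respiratory", "neurodev_delay", "death")


class ParameterError(ValueError):
    """Raised for invalid parameter values or malformed parameter files."""


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its plausible range (same units as the point)."""

    point: float
    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def is_degenerate(self) -> bool:
        return self.high == self.low

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.point, self.low, self.high)


def _est(point: float, low: float, high: float) -> Estimate:
    return Estimate(point=point, low=low, high=high)


@dataclass(frozen=True)
class AcuteDiseaseParams:
    """Acute respiratory disease: probabilities per arm, utility, cost.

    The acute utility decrement applies for ``duration_weeks`` (the latency
    from delivery to 40 weeks gestation); the cost is a one-time expense.
    """

    prob_no_acs: Estimate
    prob_acs: Estimate
    utility: Estimate
    duration_weeks: float
    cost: Estimate


@dataclass(frozen=True)
class ChronicOutcomeParams:
    """One long-term outcome: probabilities per arm, utility, duration, cost.

    ``cost_timing`` distinguishes one-time year-0 costs (childhood death)
    from lifetime costs spread uniformly over the state duration and
    discounted (chronic respiratory disease, neurodevelopmental delay).
    """

    name: str
    prob_no_acs: Estimate
    prob_acs: Estimate
    utility: Estimate
    duration_years: float
    cost: Estimate
    cost_timing: str = "spread_over_duration"


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    currency_year: int = 2011
    life_expectancy_years: float = 78.2
    healthy_utility: float = 1.0
    # Future QALYs are discounted at the same annual rate as costs by
    # default; set False to accrue undiscounted life years.
    discount_qalys: bool = True

    @property
    def qaly_rate(self) -> float:
        return self.discount_rate if self.discount_qalys else 0.0


@dataclass(frozen=True)
class ParameterSet:
    """Complete model inputs for one gestational-age week."""

    ga_week: int
    acute: AcuteDiseaseParams
    chronic: tuple[ChronicOutcomeParams, ...]
    delivery_cost_no_acs: Estimate
    delivery_cost_acs: Estimate
    settings: EconomicSettings = field(default_factory=EconomicSettings)

    def chronic_by_name(self, name: str) -> ChronicOutcomeParams:
        for c in self.chronic:
            if c.name == name:
                return c
        raise ParameterError(
            f"unknown chronic outcome {name!r}; valid names: {CHRONIC_NAMES}"
        )

    @property
    def chronic_respiratory(self) -> ChronicOutcomeParams:
        return self.chronic_by_name("chronic_respiratory")

    @property
    def neurodev_delay(self) -> ChronicOutcomeParams:
        return self.chronic_by_name("neurodev_delay")

    @property
    def death(self) -> ChronicOutcomeParams:
        return self.chronic_by_name("death")


# ---------------------------------------------------------------------------
# Built-in published estimates (2011 USD)
# ---------------------------------------------------------------------------

_ACUTE_PROB_NO_ACS = {
    34: (0.1312, 0.041, 0.2132),
    35: (0.064, 0.02, 0.104),
    36: (0.032, 0.01, 0.052),
}
_ACUTE_PROB_ACS = {
    34: (0.064, 0.02, 0.104),
    35: (0.032, 0.01, 0.052),
    36: (0.0192, 0.006, 0.0312),
}
_ACUTE_UTILITY = (0.87, 0.79, 0.93)
_ACUTE_DURATION_WEEKS = {34: 6.0, 35: 5.0, 36: 4.0}  # latency to 40 weeks
_ACUTE_COST = {
    34: (2505.0, 334.0, 50657.0),
    35: (1081.0, 315.0, 31866.0),
    36: (863.0, 305.0, 18370.0),
}

# Long-term outcomes apply identically at every late-preterm week (the
# ACS relative risks were only available for all gestational ages pooled).
_CHRONIC = {
    "chronic_respiratory": dict(
        prob_no_acs=(0.07, 0.03, 0.14),
        prob_acs=(0.0602, 0.0258, 0.1204),
        utility=(0.88, 0.80, 0.94),
        duration_years=78.2,
        cost=(56641.0, 5919.0, 74217.0),
        cost_timing="spread_over_duration",
    ),
    "neurodev_delay": dict(
        prob_no_acs=(0.00246, 0.0022, 0.0028),
        prob_acs=(0.0015744, 0.001408, 0.001792),
        utility=(0.76, 0.66, 0.84),
        duration_years=17.0,
        cost=(270790.0, 135395.0, 541582.0),
        cost_timing="spread_over_duration",
    ),
    "death": dict(
        prob_no_acs=(0.00642, 0.0059, 0.0069),
        prob_acs=(0.0043656, 0.004012, 0.004692),
        utility=(0.01, 0.001, 0.02),
        duration_years=78.2,
        cost=(56500.0, 27960.0, 83881.0),
        cost_timing="one_time_year0",
    ),
}

_DELIVERY_COST_NO_ACS = (8449.0, 5452.0, 13980.0)
_DELIVERY_COST_ACS = (16277.0, 11414.0, 17628.0)


def builtin_parameter_set(ga_week: int) -> ParameterSet:
    """Return the built-in published parameter set for a gestational-age week.

    Acute-disease probabilities, costs and durations are week-specific;
    the long-term outcome parameters are shared across 34/35/36 weeks.
    """
    if ga_week not in GA_WEEKS:
        raise ParameterError(
            f"unsupported gestational age week {ga_week}; valid values: {GA_WEEKS}"
        )
    acute = AcuteDiseaseParams(
        prob_no_acs=_est(*_ACUTE_PROB_NO_ACS[ga_week]),
        prob_acs=_est(*_ACUTE_PROB_ACS[ga_week]),
        utility=_est(*_ACUTE_UTILITY),
        duration_weeks=_ACUTE_DURATION_WEEKS[ga_week],
        cost=_est(*_ACUTE_COST[ga_week]),
    )
    chronic = tuple(
        ChronicOutcomeParams(
            name=name,
            prob_no_acs=_est(*spec["prob_no_acs"]),
            prob_acs=_est(*spec["prob_acs"]),
            utility=_est(*spec["utility"]),
            duration_years=spec["duration_years"],
            cost=_est(*spec["cost"]),
            cost_timing=spec["cost_timing"],
        )
        for name, spec in _CHRONIC.items()
    )
    return ParameterSet(
        ga_week=ga_week,
        acute=acute,
        chronic=chronic,
        delivery_cost_no_acs=_est(*_DELIVERY_COST_NO_ACS),
        delivery_cost_acs=_est(*_DELIVERY_COST_ACS),
        settings=EconomicSettings(),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _iter_estimates(params: ParameterSet) -> Iterator[tuple[str, Estimate, str]]:
    """Yield (dot-path, estimate, domain) for every Estimate in the set.

    domain is one of 'probability', 'utility', 'cost'.
    """
    yield "acute.prob_no_acs", params.acute.prob_no_acs, "probability"
    yield "acute.prob_acs", params.acute.prob_acs, "probability"
    yield "acute.utility", params.acute.utility, "utility"
    yield "acute.cost", params.acute.cost, "cost"
    for c in params.chronic:
        yield f"chronic.{c.name}.prob_no_acs", c.prob_no_acs, "probability"
        yield f"chronic.{c.name}.prob_acs", c.prob_acs, "probability"
        yield f"chronic.{c.name}.utility", c.utility, "utility"
        yield f"chronic.{c.name}.cost", c.cost, "cost"
    yield "delivery_cost_no_acs", params.delivery_cost_no_acs, "cost"
    yield "delivery_cost_acs", params.delivery_cost_acs, "cost"


def validate_parameter_set(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid).

    Structural problems (bounds, orderings, per-arm outcome sums exceeding 1)
    are reported here.  An ACS-arm adverse probability exceeding its no-ACS
    counterpart is legitimate under sampling uncertainty and is reported by
    :func:`parameter_warnings` instead.
    """
    violations: list[str] = []
    if params.ga_week not in GA_WEEKS:
        violations.append(
            f"ga_week: {params.ga_week} not in supported weeks {GA_WEEKS}"
        )
    for path, est, domain in _iter_estimates(params):
        if not (est.low <= est.point <= est.high):
            violations.append(
                f"{path}: range ordering violated (low {est.low} <= point "
                f"{est.point} <= high {est.high} required)"
            )
        if domain in ("probability", "utility"):
            if not (0.0 <= est.low and est.high <= 1.0):
                violations.append(
                    f"{path}: {domain} values must lie in [0, 1], got "
                    f"({est.point}, {est.low}, {est.high})"
                )
        elif domain == "cost":
            if est.low < 0 or est.point < 0:
                violations.append(f"{path}: cost must be nonnegative")
    if params.acute.duration_weeks <= 0:
        violations.append("acute.duration_weeks: must be positive")
    names = [c.name for c in params.chronic]
    if sorted(names) != sorted(CHRONIC_NAMES):
        violations.append(
            f"chronic: expected exactly one of each of {CHRONIC_NAMES}, got {names}"
        )
        return violations  # remaining checks assume the standard trio
    for c in params.chronic:
        if c.duration_years <= 0:
            violations.append(f"chronic.{c.name}.duration_years: must be positive")
        if c.cost_timing not in ("one_time_year0", "spread_over_duration"):
            violations.append(
                f"chronic.{c.name}.cost_timing: unknown timing {c.cost_timing!r}"
            )
    for arm in ("prob_no_acs", "prob_acs"):
        p_death = getattr(params.death, arm).point
        p_delay = getattr(params.neurodev_delay, arm).point
        if p_death + p_delay > 1.0:
            violations.append(
                f"{arm}: death+delay > 1 ({p_death} + {p_delay}); the long-term "
                "state probabilities must admit a nonnegative healthy remainder"
            )
    return violations


def parameter_warnings(params: ParameterSet) -> list[str]:
    """Non-fatal oddities: ACS-arm adverse risk above the no-ACS arm."""
    notes = []
    pairs = [("acute", params.acute.prob_no_acs, params.acute.prob_acs)] + [
        (f"chronic.{c.name}", c.prob_no_acs, c.prob_acs) for c in params.chronic
    ]
    for path, p_no, p_acs in pairs:
        if p_acs.point > p_no.point:
            notes.append(
                f"{path}: ACS-arm probability {p_acs.point} exceeds no-ACS "
                f"probability {p_no.point} (effect direction reversed)"
            )
    return notes


def require_valid(params: ParameterSet) -> ParameterSet:
    """Raise :class:`ParameterError` if the set violates any invariant."""
    violations = validate_parameter_set(params)
    if violations:
        raise ParameterError("; ".join(violations))
    return params


# ---------------------------------------------------------------------------
# Partial-course transform
# ---------------------------------------------------------------------------

def _halve_reduction(p_no: Estimate, p_acs: Estimate) -> Estimate:
    """ACS-arm estimate with half the absolute risk reduction, per component."""
    return Estimate(
        point=p_no.point - 0.5 * (p_no.point - p_acs.point),
        low=p_no.low - 0.5 * (p_no.low - p_acs.low),
        high=p_no.high - 0.5 * (p_no.high - p_acs.high),
    )


def to_partial_course(params: ParameterSet) -> ParameterSet:
    """Model an interrupted (single-dose) steroid course.

    Each adverse outcome retains only half the absolute risk reduction:
    p_acs' = p_no_acs - 0.5 (p_no_acs - p_acs).  Delivery costs and every
    other field are unchanged; the downstream cost offsets are automatically
    halved through the halved risk reductions.
    """
    acute = replace(
        params.acute,
        prob_acs=_halve_reduction(params.acute.prob_no_acs, params.acute.prob_acs),
    )
    chronic = tuple(
        replace(c, prob_acs=_halve_reduction(c.prob_no_acs, c.prob_acs))
        for c in params.chronic
    )
    return replace(params, acute=acute, chronic=chronic)


# ---------------------------------------------------------------------------
# Serialization (YAML / JSON)
# ---------------------------------------------------------------------------

def _estimate_to_dict(e: Estimate) -> dict:
    return {"point": e.point, "low": e.low, "high": e.high}


def _estimate_from_dict(d: dict, key: str) -> Estimate:
    if not isinstance(d, dict):
        raise ParameterError(f"{key}: expected a mapping with point/low/high")
    try:
        return Estimate(
            point=float(d["point"]), low=float(d["low"]), high=float(d["high"])
        )
    except KeyError as exc:
        raise ParameterError(f"{key}: missing field {exc.args[0]!r}") from None
    except (TypeError, ValueError):
        raise ParameterError(f"{key}: point/low/high must be numbers") from None


def parameter_set_to_dict(params: ParameterSet) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "ga_week": params.ga_week,
        "acute": {
            "prob_no_acs": _estimate_to_dict(params.acute.prob_no_acs),
            "prob_acs": _estimate_to_dict(params.acute.prob_acs),
            "utility": _estimate_to_dict(params.acute.utility),
            "duration_weeks": params.acute.duration_weeks,
            "cost": _estimate_to_dict(params.acute.cost),
        },
        "delivery_costs": {
            "no_acs": _estimate_to_dict(params.delivery_cost_no_acs),
            "acs": _estimate_to_dict(params.delivery_cost_acs),
        },
        "settings": dataclasses.asdict(params.settings),
    }
    for c in params.chronic:
        d[c.name] = {
            "prob_no_acs": _estimate_to_dict(c.prob_no_acs),
            "prob_acs": _estimate_to_dict(c.prob_acs),
            "utility": _estimate_to_dict(c.utility),
            "duration_years": c.duration_years,
            "cost": _estimate_to_dict(c.cost),
            "cost_timing": c.cost_timing,
        }
    return d


def parameter_set_from_dict(d: dict) -> ParameterSet:
    if not isinstance(d, dict):
        raise ParameterError("parameter file must contain a mapping at top level")
    for key in ("ga_week", "acute", "delivery_costs", *CHRONIC_NAMES):
        if key not in d:
            raise ParameterError(f"missing required key {key!r}")
    a = d["acute"]
    try:
        acute = AcuteDiseaseParams(
            prob_no_acs=_estimate_from_dict(a["prob_no_acs"], "acute.prob_no_acs"),
            prob_acs=_estimate_from_dict(a["prob_acs"], "acute.prob_acs"),
            utility=_estimate_from_dict(a["utility"], "acute.utility"),
            duration_weeks=float(a["duration_weeks"]),
            cost=_estimate_from_dict(a["cost"], "acute.cost"),
        )
    except KeyError as exc:
        raise ParameterError(f"acute: missing field {exc.args[0]!r}") from None
    chronic = []
    for name in CHRONIC_NAMES:
        c = d[name]
        try:
            chronic.append(
                ChronicOutcomeParams(
                    name=name,
                    prob_no_acs=_estimate_from_dict(
                        c["prob_no_acs"], f"{name}.prob_no_acs"
                    ),
                    prob_acs=_estimate_from_dict(c["prob_acs"], f"{name}.prob_acs"),
                    utility=_estimate_from_dict(c["utility"], f"{name}.utility"),
                    duration_years=float(c["duration_years"]),
                    cost=_estimate_from_dict(c["cost"], f"{name}.cost"),
                    cost_timing=c.get("cost_timing", "spread_over_duration"),
                )
            )
        except KeyError as exc:
            raise ParameterError(f"{name}: missing field {exc.args[0]!r}") from None
    dc = d["delivery_costs"]
    try:
        no_acs_cost = _estimate_from_dict(dc["no_acs"], "delivery_costs.no_acs")
        acs_cost = _estimate_from_dict(dc["acs"], "delivery_costs.acs")
    except KeyError as exc:
        raise ParameterError(
            f"delivery_costs: missing field {exc.args[0]!r}"
        ) from None
    settings = EconomicSettings(**d.get("settings", {}))
    params = ParameterSet(
        ga_week=int(d["ga_week"]),
        acute=acute,
        chronic=tuple(chronic),
        delivery_cost_no_acs=no_acs_cost,
        delivery_cost_acs=acs_cost,
        settings=settings,
    )
    require_valid(params)
    for note in parameter_warnings(params):
        warnings.warn(note, stacklevel=2)
    return params


def save_parameter_set(params: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet to YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    d = parameter_set_to_dict(params)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        raise ParameterError(f"unsupported parameter file extension {path.suffix!r}")
    return path


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        try:
            d = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParameterError(f"malformed YAML in {path}: {exc}") from None
    elif path.suffix == ".json":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParameterError(f"malformed JSON in {path}: {exc}") from None
    else:
        raise ParameterError(f"unsupported parameter file extension {path.suffix!r}")
    return parameter_set_from_dict(d)
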