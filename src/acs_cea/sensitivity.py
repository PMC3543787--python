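"""One-way (univariable) sensitivity analysis.

Parameters are addressed by dot-paths into the ParameterSet (e.g.
``chronic.chronic_respiratory.prob_acs`` or ``acute.cost``); each resolves
to an Estimate whose point value is swept across its plausible [low, high]
range with every other input held at base case.  Threshold finding bisects
on the cost-effectiveness *decision* (acceptable at the willingness-to-pay
threshold or not, including dominance cases), which is robust to the ICER's
discontinuity where incremental effectiveness crosses zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cea import CEAResult, compare
from .parameters import Estimate, ParameterSet, _iter_estimates

DEFAULT_N_POINTS = 21
DEFAULT_TOLERANCE = 1e-4
MAX_BISECTIONS = 60


@dataclass(frozen=True)
class SweepResult:
    parameter_id: str
    values: tuple[float, ...]
    icers: tuple[float | None, ...]
    classifications: tuple[str, ...]


@dataclass(frozen=True)
class ThresholdResult:
    parameter_id: str
    threshold_value: float | None
    direction: str  # crosses_above_wtp | crosses_below_wtp | no_crossing
    bracket: tuple[float, float]


def estimate_ids(params: ParameterSet) -> list[str]:
    """All valid parameter dot-paths, in canonical order."""
    return [path for path, _, _ in _iter_estimates(params)]


def get_estimate(params: ParameterSet, parameter_id: str) -> Estimate:
    for path, est, _ in _iter_estimates(params):
        if path == parameter_id:
            return est
    raise KeyError(
        f"unknown parameter id {parameter_id!r}; valid ids: {estimate_ids(params)}"
    )


def set_point(params: ParameterSet, parameter_id: str, value: float) -> ParameterSet:
    """Return a copy with the addressed Estimate's point set to ``value``.

    The range is widened if needed so low <= point <= high stays true.
    """
    old = get_estimate(params, parameter_id)
    new = Estimate(point=value, low=min(old.low, value), high=max(old.high, value))
    parts = parameter_id.split(".")
    if parts[0] == "acute":
        return replace(params, acute=replace(params.acute, **{parts[1]: new}))
    if parts[0] == "chronic":
        name, field = parts[1], parts[2]
        chronic = tuple(
            replace(c, **{field: new}) if c.name == name else c
            for c in params.chronic
        )
        return replace(params, chronic=chronic)
    return replace(params, **{parts[0]: new})


def _acceptable(result: CEAResult) -> bool:
    return result.classification in ("acs_dominant", "acs_cost_effective")


def one_way_sweep(
    params: ParameterSet, parameter_id: str, n_points: int = DEFAULT_N_POINTS
) -> SweepResult:
    """ICER and classification at evenly spaced values across the range."""
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    est = get_estimate(params, parameter_id)
    values = np.linspace(est.low, est.high, n_points)
    icers, classifications = [], []
    for v in values:
        res = compare(set_point(params, parameter_id, float(v)), validate=False)
        icers.append(res.icer)
        classifications.append(res.classification)
    return SweepResult(
        parameter_id=parameter_id,
        values=tuple(float(v) for v in values),
        icers=tuple(icers),
        classifications=tuple(classifications),
    )


def find_threshold(
    params: ParameterSet,
    parameter_id: str,
    bracket: tuple[float, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ThresholdResult:
    """Bisect for the parameter value where the WTP decision flips.

    ``bracket`` defaults to the parameter's [low, high] range.  Returns
    no_crossing when both endpoints yield the same decision.  The threshold
    is the midpoint of the final bracket, whose width is at most
    ``tolerance`` times the initial bracket width.
    """
    est = get_estimate(params, parameter_id)
    lo, hi = bracket if bracket is not None else (est.low, est.high)
    if not hi > lo:
        raise ValueError(f"invalid bracket ({lo}, {hi}): need lo < hi")

    def decision(v: float) -> bool:
        return _acceptable(compare(set_point(params, parameter_id, v), validate=False))

    d_lo, d_hi = decision(lo), decision(hi)
    if d_lo == d_hi:
        return ThresholdResult(parameter_id, None, "no_crossing", (lo, hi))
    direction = "crosses_above_wtp" if d_lo else "crosses_below_wtp"
    width0 = hi - lo
    for _ in range(MAX_BISECTIONS):
        if hi - lo <= tolerance * width0:
            break
        mid = 0.5 * (lo + hi)
        if decision(mid) == d_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(parameter_id, 0.5 * (lo + hi), direction, (lo, hi))


def tornado_table(
    params: ParameterSet,
) -> list[tuple[str, float | None, float | None]]:
    """ICER at each parameter's range endpoints, sorted by descending span.

    Rows are (parameter_id, icer_at_low, icer_at_high); an entry is None
    when incremental effectiveness is exactly zero there.
    """
    rows = []
    for pid in estimate_ids(params):
        est = get_estimate(params, pid)
        icer_low = compare(set_point(params, pid, est.low), validate=False).icer
        icer_high = compare(set_point(params, pid, est.high), validate=False).icer
        rows.append((pid, icer_low, icer_high))

    base_icer = compare(params, validate=False).icer or 0.0

    def span(row):
        _, lo, hi = row
        lo = base_icer if lo is None else lo
        hi = base_icer if hi is None else hi
        return abs(hi - lo)

    return sorted(rows, key=span, reverse=True)
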