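"""Convert reported evidence into log-scale effect estimates.

Published studies report a marker's prognostic effect in three forms: a
hazard ratio with a 95% CI, a 2x2 contingency table, or only a pair of
Kaplan-Meier curves. Everything is normalized to a natural-log effect with
a standard error (:class:`~hccmeta.records.EffectEstimate`) before pooling.

KM-curve reconstruction follows the piecewise-exponential observed-drop
approach: the common follow-up span is split into intervals, within each
interval the arm-specific cumulative hazard increment is read off the
digitized curve as ``-ln S(t2)/S(t1)``, the interval log hazard ratio is the
log of the ratio of increments, its variance is ``1/d_high + 1/d_low`` with
event counts estimated from the numbers at risk, and intervals are combined
by inverse-variance weighting. This is a reconstruction, not a re-fit of
patient data, and its provenance is flagged on the returned estimate.
"""

from __future__ import annotations

import csv
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, EffectLookupError, ParseError
from .records import (
    Adjustment,
    ContingencyTable,
    EffectEstimate,
    EffectOrigin,
    EffectSource,
    KMCurve,
    Outcome,
    Scale,
    Z95,
)

#: Precedence of reported adjustments: multivariate estimates account for
#: confounders and win; curve reconstructions are a last resort.
_ADJUSTMENT_RANK = {
    Adjustment.MULTIVARIATE: 0,
    Adjustment.UNIVARIATE: 1,
    Adjustment.CURVE_DERIVED: 2,
}


def loghr_from_ci(
    hr: float,
    ci_low: float,
    ci_high: float,
    study_id: str = "",
    outcome: str = "OS",
) -> EffectEstimate:
    """Log hazard ratio and SE from a reported HR with symmetric 95% CI.

    ``se = (ln ci_high - ln ci_low) / (2 * 1.959964)``. A degenerate CI
    (zero width) is rejected: it carries no uncertainty information.
    """
    if not (0 < ci_low <= hr <= ci_high):
        raise DomainError(
            f"HR/CI must satisfy 0 < ci_low <= hr <= ci_high, got ({hr}, {ci_low}, {ci_high})"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if se <= 0:
        raise DomainError(f"degenerate CI ({ci_low}, {ci_high}): zero-width interval has no SE")
    return EffectEstimate(
        study_id=study_id,
        outcome_or_feature=outcome,
        log_effect=math.log(hr),
        se=se,
        scale=Scale.LOG_HR,
        source=EffectOrigin.REPORTED_CI,
    )


def logor_from_table(table: ContingencyTable, correction: float = 0.5) -> EffectEstimate:
    """Woolf log odds ratio from a 2x2 table.

    With any zero cell, ``correction`` (default 0.5) is added to all four
    cells; otherwise cells are used as-is. ``se = sqrt(1/a+1/b+1/c+1/d)``.
    """
    if correction < 0:
        raise DomainError(f"continuity correction must be nonnegative, got {correction}")
    if table.a + table.b < 1 or table.c + table.d < 1:
        raise DomainError(
            f"study {table.study_id!r}, feature {table.feature!r}: "
            "need at least one exposed and one unexposed patient"
        )
    cells = [float(x) for x in table.cells]
    if any(x == 0 for x in cells):
        if correction == 0:
            raise DomainError(
                f"study {table.study_id!r}, feature {table.feature!r}: "
                "zero cell with correction 0 gives an infinite log OR"
            )
        cells = [x + correction for x in cells]
    a, b, c, d = cells
    return EffectEstimate(
        study_id=table.study_id,
        outcome_or_feature=table.feature,
        log_effect=math.log(a * d / (b * c)),
        se=math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
        scale=Scale.LOG_OR,
        source=EffectOrigin.CONTINGENCY,
    )


def _step_survival(curve: KMCurve, t: float) -> float:
    """KM curves are step functions; value at the greatest sampled time <= t."""
    times = np.asarray(curve.times)
    idx = int(np.searchsorted(times, t, side="right")) - 1
    return curve.survival[max(idx, 0)]


def _at_risk_at(curve: KMCurve, t: float) -> Optional[float]:
    if curve.at_risk_times is None:
        return None
    times = np.asarray([p[0] for p in curve.at_risk_times])
    idx = int(np.searchsorted(times, t, side="right")) - 1
    if idx < 0:
        return float(curve.at_risk_times[0][1])
    return float(curve.at_risk_times[idx][1])


def loghr_from_km(
    curve_high: KMCurve,
    curve_low: KMCurve,
    n_intervals: int = 5,
    censoring_rate: float = 0.0,
    study_id: str = "",
    outcome: str = "OS",
) -> EffectEstimate:
    """Reconstruct a log hazard ratio from a pair of digitized KM curves.

    Parameters
    ----------
    curve_high, curve_low
        Marker-high and marker-low arms.
    n_intervals
        Number of equal-width intervals over the common span (default 5).
        Intervals in which either arm shows no drop are merged forward so
        every contributing interval has events in both arms.
    censoring_rate
        Assumed exponential censoring rate (per month) used to deplete the
        at-risk count between intervals when the figure's numbers-at-risk
        row is unavailable; 0 assumes no censoring before the span end.
    """
    if n_intervals < 1:
        raise DomainError("n_intervals must be >= 1")
    t_end = min(curve_high.times[-1], curve_low.times[-1])
    if t_end <= 0:
        raise DomainError("curves have no overlapping positive time span")
    # stay where both survival functions are positive (log of 0 is undefined)
    for curve in (curve_high, curve_low):
        positive = [t for t, s in curve.points if s > 0]
        t_end = min(t_end, positive[-1]) if positive else 0.0
    if t_end <= 0:
        raise DomainError("no common span with positive survival in both arms")
    if _step_survival(curve_high, t_end) >= 1.0 and _step_survival(curve_low, t_end) >= 1.0:
        raise DomainError("degenerate curves: no drop in either arm over the common span")

    bounds = np.linspace(0.0, t_end, n_intervals + 1)
    s_high = np.array([_step_survival(curve_high, t) for t in bounds])
    s_low = np.array([_step_survival(curve_low, t) for t in bounds])

    # merge forward until both arms have a positive drop within the interval
    log_hrs: List[float] = []
    variances: List[float] = []
    risk_h = float(curve_high.n_at_risk_initial)
    risk_l = float(curve_low.n_at_risk_initial)
    start = 0
    for end in range(1, len(bounds)):
        h_high = math.log(s_high[start]) - math.log(s_high[end])
        h_low = math.log(s_low[start]) - math.log(s_low[end])
        if h_high <= 0 or h_low <= 0:
            continue  # extend the interval
        nh = _at_risk_at(curve_high, bounds[start])
        nl = _at_risk_at(curve_low, bounds[start])
        nh = risk_h if nh is None else nh
        nl = risk_l if nl is None else nl
        d_high = nh * (1.0 - s_high[end] / s_high[start])
        d_low = nl * (1.0 - s_low[end] / s_low[start])
        if d_high <= 0 or d_low <= 0:
            continue
        log_hrs.append(math.log(h_high / h_low))
        variances.append(1.0 / d_high + 1.0 / d_low)
        dt = bounds[end] - bounds[start]
        keep = math.exp(-censoring_rate * dt)
        risk_h = (nh - d_high) * keep
        risk_l = (nl - d_low) * keep
        start = end
    if not log_hrs:
        raise DomainError("degenerate curves: no interval with events in both arms")

    w = np.array([1.0 / v for v in variances])
    est = float(np.dot(w, log_hrs) / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    return EffectEstimate(
        study_id=study_id,
        outcome_or_feature=outcome,
        log_effect=est,
        se=se,
        scale=Scale.LOG_HR,
        source=EffectOrigin.KM_CURVE,
    )


def select_effect(sources: Sequence[EffectSource], outcome: Outcome) -> EffectSource:
    """Pick the evidence source for an endpoint by adjustment precedence.

    Multivariate beats univariate beats curve-derived; ties resolve to the
    first listed source, so selection is deterministic.
    """
    outcome = Outcome(outcome)
    matching = [s for s in sources if s.outcome == outcome]
    if not matching:
        raise EffectLookupError(f"no effect source reports outcome {outcome.value!r}")
    return min(matching, key=lambda s: _ADJUSTMENT_RANK[s.adjustment])


def effect_from_source(
    source: EffectSource,
    study_id: str = "",
    n_intervals: int = 5,
) -> EffectEstimate:
    """Materialize an :class:`EffectEstimate` from a single evidence source."""
    if source.hr is not None:
        return loghr_from_ci(
            source.hr, source.ci_low, source.ci_high,
            study_id=study_id, outcome=source.outcome.value,
        )
    high, low = source.km_curves
    return loghr_from_km(high, low, n_intervals=n_intervals, study_id=study_id, outcome=source.outcome.value)


def load_km_curves(path, n_at_risk_initial: Optional[Dict[str, int]] = None) -> Dict[str, KMCurve]:
    """Read digitized curves from a CSV with columns arm,time,survival[,at_risk].

    Returns one curve per arm label. Initial numbers at risk come from the
    ``at_risk`` column at time 0 when present, otherwise from the
    ``n_at_risk_initial`` mapping.
    """
    arms: Dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"arm", "time", "survival"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: header must contain arm,time,survival")
        has_risk = "at_risk" in reader.fieldnames
        for row in reader:
            line = reader.line_num
            try:
                t, s = float(row["time"]), float(row["survival"])
            except ValueError as exc:
                raise ParseError(f"{path}: line {line}: non-numeric time/survival") from exc
            entry = arms.setdefault(row["arm"], {"points": [], "risk": []})
            entry["points"].append((t, s))
            if has_risk and row["at_risk"].strip():
                entry["risk"].append((t, float(row["at_risk"])))
    curves: Dict[str, KMCurve] = {}
    for arm, entry in arms.items():
        risk = entry["risk"]
        if risk and risk[0][0] == 0.0:
            n0 = int(risk[0][1])
        elif n_at_risk_initial and arm in n_at_risk_initial:
            n0 = n_at_risk_initial[arm]
        else:
            raise ParseError(f"{path}: arm {arm!r}: no at_risk at time 0 and no n_at_risk_initial given")
        curves[arm] = KMCurve(
            arm_label=arm,
            points=tuple(entry["points"]),
            n_at_risk_initial=n0,
            at_risk_times=tuple(risk) if risk else None,
        )
    return curves
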