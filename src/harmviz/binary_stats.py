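"""Absolute summaries and comparative effect estimates for binary/count harms.

These are the numbers behind the dot plot, the stacked bar chart and the bar
chart: per-event counts of affected participants, and two-arm effect measures
(relative risk, odds ratio, risk difference, incidence rate ratio) with Wald
confidence intervals.

Interval construction is Wald throughout — on the log scale for the ratio
measures (the Katz interval for the relative risk) and on the identity scale
for the risk difference — with half-width z(1 - alpha/2) x SE.  When exactly
one arm records zero events, the standard continuity correction adds half an
event to each group (numerator and denominator) before estimation; rows with
zero events in both arms admit no ratio estimate and are reported as dropped.
No multiplicity adjustment is applied: these intervals flag potential signals
for further investigation and are not a proxy for hypothesis testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialDataset

__all__ = [
    "RELATIVE_RISK",
    "ODDS_RATIO",
    "RISK_DIFFERENCE",
    "RATE_RATIO",
    "NoEstimateError",
    "ArmEventCount",
    "EventSummary",
    "EffectEstimate",
    "summarize_by_event",
    "summaries_to_frame",
    "effect_estimate",
    "incidence_rate_ratio",
    "order_for_dot_plot",
    "estimates_to_frame",
    "dot_plot_estimates",
]

RELATIVE_RISK = "relative risk"
ODDS_RATIO = "odds ratio"
RISK_DIFFERENCE = "risk difference"
RATE_RATIO = "incidence rate ratio"

_RATIO_MEASURES = {RELATIVE_RISK, ODDS_RATIO, RATE_RATIO}


class NoEstimateError(ValueError):
    """No comparative estimate exists (e.g. zero events in both arms)."""


@dataclass(frozen=True)
class ArmEventCount:
    """Counts for one arm: affected participants, event records, percent."""

    arm_size: int
    n_participants: int
    n_events: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_participants / self.arm_size

    def __post_init__(self) -> None:
        if not 0 <= self.n_participants <= self.arm_size:
            raise ValueError("participants with events cannot exceed arm size")
        if self.n_events < self.n_participants:
            raise ValueError("event records cannot be fewer than affected participants")


@dataclass(frozen=True)
class EventSummary:
    """Per-arm absolute summary for one event term or grouping."""

    label: str
    per_arm: Mapping[str, ArmEventCount]


@dataclass(frozen=True)
class EffectEstimate:
    """A two-arm comparative estimate with its Wald confidence interval.

    ``inputs`` records the 2x2 counts (a, n1, b, n2) or the (events,
    exposure-time) pairs the estimate was computed from, after any continuity
    correction; ``corrected`` flags whether that correction was applied.
    """

    measure: str
    point: float
    ci_low: float
    ci_high: float
    corrected: bool
    inputs: dict
    alpha: float = 0.05

    @property
    def null_value(self) -> float:
        """Value of no difference: 1 for ratio measures, 0 for differences."""
        return 0.0 if self.measure == RISK_DIFFERENCE else 1.0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")
        if self.measure in _RATIO_MEASURES and self.point <= 0:
            raise ValueError("ratio measures must be positive")


def summarize_by_event(dataset: TrialDataset, by: str = "group") -> list[EventSummary]:
    """Absolute per-arm summary for every distinct event term or grouping.

    Percentages use the arm roster sizes as denominators; arms with no
    occurrences of an event contribute explicit zero counts.
    """
    if by not in ("term", "group"):
        raise ValueError("by must be 'term' or 'group'")
    sizes = dataset.arm_sizes()
    arm_of = dataset.arm_by_participant()
    ev = dataset.events.assign(arm=lambda d: d["participant_id"].map(arm_of))
    out = []
    for label in dict.fromkeys(ev[by]):
        rows = ev[ev[by] == label]
        per_arm = {}
        for arm, size in sizes.items():
            mine = rows[rows["arm"] == arm]
            per_arm[arm] = ArmEventCount(
                arm_size=size,
                n_participants=mine["participant_id"].nunique(),
                n_events=len(mine),
            )
        out.append(EventSummary(label=label, per_arm=per_arm))
    return out


def summaries_to_frame(summaries: Sequence[EventSummary]) -> pd.DataFrame:
    """Tidy frame of EventSummary objects (the dot plot's data table)."""
    rows = [
        (s.label, arm, c.arm_size, c.n_participants, c.n_events, c.percent)
        for s in summaries
        for arm, c in s.per_arm.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["label", "arm", "arm_size", "n_participants", "n_events", "percent"],
    )


def _z(alpha: float) -> float:
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def effect_estimate(
    a: float,
    n1: float,
    b: float,
    n2: float,
    measure: str = RELATIVE_RISK,
    alpha: float = 0.05,
    correction: bool = True,
) -> EffectEstimate:
    """Two-arm effect estimate from 2x2 counts with a Wald interval.

    Parameters
    ----------
    a, n1
        Affected participants and arm size in the comparison (treatment) arm.
    b, n2
        The same in the reference (control) arm.
    measure
        One of ``relative risk``, ``odds ratio``, ``risk difference``.
    correction
        When exactly one of ``a``, ``b`` is zero, add 0.5 to each of a, b,
        n1, n2 before estimation (half an event to each group's numerator
        and denominator) and flag the result ``corrected``.

    Raises
    ------
    NoEstimateError
        If both arms record zero events: the row should be dropped from
        comparative displays (with a footnote), not estimated.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("arm sizes must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("event counts must lie in [0, arm size]")
    if measure not in (RELATIVE_RISK, ODDS_RATIO, RISK_DIFFERENCE):
        raise ValueError(f"unknown measure {measure!r}")
    if a == 0 and b == 0:
        raise NoEstimateError("zero events in both arms: no comparative estimate")

    corrected = bool(correction) and ((a == 0) != (b == 0))
    if corrected:
        a, b, n1, n2 = a + 0.5, b + 0.5, n1 + 0.5, n2 + 0.5

    z = _z(alpha)
    p1, p2 = a / n1, b / n2
    inputs = {"a": a, "n1": n1, "b": b, "n2": n2}

    if measure == RISK_DIFFERENCE:
        point = p1 - p2
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        lo, hi = point - z * se, point + z * se
    elif measure == RELATIVE_RISK:
        if a == 0 or b == 0:
            raise NoEstimateError(
                "zero events in one arm with correction disabled: no ratio estimate"
            )
        point = p1 / p2
        se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
        lo, hi = point * math.exp(-z * se), point * math.exp(z * se)
    else:  # odds ratio
        cells = (a, n1 - a, b, n2 - b)
        if cells[0] == 0 or cells[2] == 0:
            raise NoEstimateError(
                "zero events in one arm with correction disabled: no ratio estimate"
            )
        point = (p1 / (1 - p1)) / (p2 / (1 - p2)) if cells[1] > 0 and cells[3] > 0 else math.inf
        if any(c == 0 for c in cells):
            se = math.inf
        else:
            se = math.sqrt(sum(1 / c for c in cells))
        if math.isinf(point):
            raise NoEstimateError("all participants affected in an arm: odds undefined")
        lo, hi = point * math.exp(-z * se), point * math.exp(z * se)

    return EffectEstimate(
        measure=measure,
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        corrected=corrected,
        inputs=inputs,
        alpha=alpha,
    )


def incidence_rate_ratio(
    events1: float,
    time1: float,
    events2: float,
    time2: float,
    alpha: float = 0.05,
    correction: bool = True,
) -> EffectEstimate:
    """Rate ratio between two arms from event counts and exposure times.

    ``time1``/``time2`` are total person-time at risk (any unit, used for
    both arms consistently).  The Wald interval uses SE = sqrt(1/events1 +
    1/events2) on the log scale; when exactly one count is zero and
    *correction* is enabled, half an event is added to both counts.
    """
    if time1 <= 0 or time2 <= 0:
        raise ValueError("exposure times must be positive")
    if events1 < 0 or events2 < 0:
        raise ValueError("event counts must be non-negative")
    if events1 == 0 and events2 == 0:
        raise NoEstimateError("zero events in both arms: no rate ratio")

    corrected = bool(correction) and ((events1 == 0) != (events2 == 0))
    if corrected:
        events1, events2 = events1 + 0.5, events2 + 0.5
    if events1 == 0 or events2 == 0:
        raise NoEstimateError(
            "zero events in one arm with correction disabled: no rate ratio"
        )

    z = _z(alpha)
    point = (events1 / time1) / (events2 / time2)
    se = math.sqrt(1 / events1 + 1 / events2)
    return EffectEstimate(
        measure=RATE_RATIO,
        point=float(point),
        ci_low=float(point * math.exp(-z * se)),
        ci_high=float(point * math.exp(z * se)),
        corrected=corrected,
        inputs={"events1": events1, "time1": time1, "events2": events2, "time2": time2},
        alpha=alpha,
    )


def order_for_dot_plot(
    estimates: Mapping[str, EffectEstimate | None],
) -> tuple[list[tuple[str, EffectEstimate]], list[str]]:
    """Order labelled estimates for display: highest point estimate at top.

    Ties break alphabetically by label.  Entries mapped to ``None`` (rows
    with no estimate, e.g. zero events in both arms) are returned separately
    so the plot can footnote them.  All estimates must share one measure.
    """
    kept = {k: v for k, v in estimates.items() if v is not None}
    dropped = sorted(k for k, v in estimates.items() if v is None)
    measures = {v.measure for v in kept.values()}
    if len(measures) > 1:
        raise ValueError(f"mixed measures cannot be ordered together: {sorted(measures)}")
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1].point, kv[0]))
    return ordered, dropped


def estimates_to_frame(ordered: Sequence[tuple[str, EffectEstimate]]) -> pd.DataFrame:
    """Tidy frame of ordered (label, estimate) pairs."""
    rows = [
        (label, e.measure, e.point, e.ci_low, e.ci_high, e.corrected)
        for label, e in ordered
    ]
    return pd.DataFrame(
        rows, columns=["label", "measure", "point", "ci_low", "ci_high", "corrected"]
    )


def dot_plot_estimates(
    summaries: Sequence[EventSummary],
    treatment_arm: str,
    control_arm: str,
    measure: str = RELATIVE_RISK,
    alpha: float = 0.05,
    correction: bool = True,
) -> tuple[list[tuple[str, EffectEstimate]], list[str]]:
    """Per-event effect estimates (treatment vs control), dot-plot ordered.

    Convenience wrapper over :func:`effect_estimate` + :func:`order_for_dot_plot`;
    double-zero events are dropped and listed second.
    """
    labelled: dict[str, EffectEstimate | None] = {}
    for s in summaries:
        t, c = s.per_arm[treatment_arm], s.per_arm[control_arm]
        try:
            labelled[s.label] = effect_estimate(
                t.n_participants, t.arm_size, c.n_participants, c.arm_size,
                measure=measure, alpha=alpha, correction=correction,
            )
        except NoEstimateError:
            labelled[s.label] = None
    return order_for_dot_plot(labelled)
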