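"""Product-limit survival, mean cumulative function, and survival-ratio bands.

Three estimators feed the time-to-event harm plots:

* :func:`km_estimate` — the Kaplan-Meier product-limit estimate of the
  probability of remaining event-free, with Greenwood variance and
  complementary log-log confidence bands (which keep the bands inside
  [0, 1] without ad-hoc clipping).
* :func:`mcf_estimate` — the non-parametric mean cumulative function for
  recurrent events: the expected cumulative number of events per participant
  over time, with the Lawless-Nadeau robust variance (which accounts for
  within-participant correlation of recurrences) and a log-scale interval.
* :func:`survival_ratio` — the ratio (or difference) of two arms'
  Kaplan-Meier estimates over the union of their event-time grids, with
  pointwise percentile bootstrap bands from participant-level resampling
  within each arm.

Competing risks are not modelled here: when a competing event (e.g. death)
precludes the harm of interest, these estimates can overstate cumulative
risk, and a cumulative-incidence analysis (Aalen-Johansen or Fine-Gray) is
the appropriate alternative.  Ties are handled by processing events before
censorings at equal times; events on the censoring day count as events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "RiskTable",
    "SurvivalRatioCurve",
    "km_estimate",
    "extended_risk_table",
    "mcf_estimate",
    "survival_ratio",
]


@dataclass
class SurvivalCurve:
    """A stepwise estimate over time: Kaplan-Meier (``kind="km"``) or mean
    cumulative function (``kind="mcf"``), with per-step variance and bands."""

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: str
    n: int
    arm: str | None = None
    alpha: float = 0.05

    @property
    def start_value(self) -> float:
        """Value at t = 0: 1 for Kaplan-Meier, 0 for the MCF."""
        return 1.0 if self.kind == "km" else 0.0

    def evaluate(self, grid: Iterable[float]) -> np.ndarray:
        """Right-continuous step evaluation at arbitrary times."""
        grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right")
        vals = np.concatenate([[self.start_value], self.estimate])
        return vals[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": self.arm,
                "time": self.times,
                "estimate": self.estimate,
                "variance": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "kind": self.kind,
            }
        )


@dataclass
class RiskTable:
    """Extended at-risk table: participants at risk, cumulatively censored,
    and cumulatively evented, per arm at each grid time."""

    timepoints: np.ndarray
    table: pd.DataFrame  # columns: arm, time, at_risk, cum_censored, cum_events

    def for_arm(self, arm: str) -> pd.DataFrame:
        return self.table[self.table["arm"] == arm].reset_index(drop=True)

    @property
    def arms(self) -> list[str]:
        return list(dict.fromkeys(self.table["arm"]))


@dataclass
class SurvivalRatioCurve:
    """Ratio (or difference) of two arms' survival estimates with pointwise
    bootstrap bands; ``excludes_unity`` flags times at which the band
    excludes the null (1 for ratios, 0 for differences)."""

    times: np.ndarray
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    excludes_unity: np.ndarray
    mode: str = "ratio"
    reference: str = "arm1"
    comparator: str = "arm2"
    n_boot: int = 1000
    seed: int | None = None
    alpha: float = 0.05

    @property
    def null_value(self) -> float:
        return 1.0 if self.mode == "ratio" else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "ratio": self.ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "excludes_unity": self.excludes_unity,
            }
        )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def _coerce_records(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with time/status columns or an iterable of pairs."""
    if isinstance(records, pd.DataFrame):
        times = records["time"].to_numpy(dtype=float)
        status = records["status"].to_numpy(dtype=int)
    else:
        arr = np.asarray(list(records), dtype=float)
        if arr.size == 0:
            return np.empty(0), np.empty(0, dtype=int)
        times, status = arr[:, 0], arr[:, 1].astype(int)
    if times.size and times.min() < 0:
        raise ValueError("times must be non-negative")
    return times, status


def _km_core(times: np.ndarray, status: np.ndarray):
    """Distinct event times with at-risk counts, deaths, S and Greenwood var."""
    order = np.argsort(times, kind="stable")
    t, s = times[order], status[order]
    event_times = np.unique(t[s == 1])
    n = len(t)
    # at risk at u: everyone with time >= u (censored at u still at risk: ties
    # process events before censorings)
    at_risk = n - np.searchsorted(t, event_times, side="left")
    d = np.array([np.sum((t == u) & (s == 1)) for u in event_times], dtype=float)
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (at_risk * (at_risk - d))
        var = surv**2 * np.cumsum(gw_terms)
    var = np.where(surv == 0.0, 0.0, var)
    return event_times, at_risk, d, surv, var


def _cloglog_bands(surv: np.ndarray, var: np.ndarray, alpha: float):
    """Complementary log-log confidence bands, degenerate at S in {0, 1}."""
    z = stats.norm.ppf(1 - alpha / 2)
    lo = surv.copy()
    hi = surv.copy()
    interior = (surv > 0) & (surv < 1) & (var > 0)
    s = surv[interior]
    se_theta = np.sqrt(var[interior]) / (s * np.abs(np.log(s)))
    lo[interior] = s ** np.exp(z * se_theta)
    hi[interior] = s ** np.exp(-z * se_theta)
    return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)


def km_estimate(records, alpha: float = 0.05, arm: str | None = None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of event-free probability.

    Parameters
    ----------
    records
        (time, status) pairs or a DataFrame with ``time``/``status`` columns
        (status 1 = event, 0 = censored), e.g. from
        :func:`~harmviz.data_model.derive_first_event_times`.
    alpha
        Two-sided band level (default 95% bands).

    The curve steps only at event times; Greenwood's formula gives the
    variance and the bands come from the complementary log-log transform.
    """
    times, status = _coerce_records(records)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one record")
    event_times, _, _, surv, var = _km_core(times, status)
    lo, hi = _cloglog_bands(surv, var, alpha)
    return SurvivalCurve(
        times=event_times, estimate=surv, variance=var, ci_low=lo, ci_high=hi,
        kind="km", n=len(times), arm=arm, alpha=alpha,
    )


def extended_risk_table(
    records_by_arm: Mapping[str, object], timepoints: Sequence[float]
) -> RiskTable:
    """At-risk / cumulatively-censored / cumulatively-evented counts per arm.

    ``timepoints`` must be increasing and start at 0.  Cumulative columns
    count events and censorings up to and including each grid time (the t = 0
    row is the boundary: full arm at risk, cumulative columns zero), and
    at-risk = arm size - (cumulative events + cumulative censored).
    """
    grid = np.asarray(list(timepoints), dtype=float)
    if grid.size == 0 or grid[0] != 0:
        raise ValueError("timepoints must start at 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rows = []
    for arm, records in records_by_arm.items():
        times, status = _coerce_records(records)
        n = len(times)
        ev = np.sort(times[status == 1])
        ce = np.sort(times[status == 0])
        cum_events = np.searchsorted(ev, grid, side="right")
        cum_cens = np.searchsorted(ce, grid, side="right")
        cum_events[grid == 0] = 0
        cum_cens[grid == 0] = 0
        at_risk = n - cum_events - cum_cens
        for t, r, c, e in zip(grid, at_risk, cum_cens, cum_events):
            rows.append((arm, float(t), int(r), int(c), int(e)))
    table = pd.DataFrame(
        rows, columns=["arm", "time", "at_risk", "cum_censored", "cum_events"]
    )
    return RiskTable(timepoints=grid, table=table)


# ---------------------------------------------------------------------------
# Mean cumulative function
# ---------------------------------------------------------------------------


def mcf_estimate(
    event_times_by_participant: Mapping[object, Sequence[float]],
    followup_by_participant: Mapping[object, float],
    alpha: float = 0.05,
    arm: str | None = None,
) -> SurvivalCurve:
    """Mean cumulative number of events per participant over time.

    At each distinct event time t the estimate increases by d(t)/Y(t), the
    number of events at t over the number of participants still under
    observation.  The variance is the Lawless-Nadeau robust estimator
    (participant-wise sums of cumulative residuals, squared), and the bands
    are log-scale so the lower bound stays non-negative.

    ``followup_by_participant`` must cover every participant in the roster
    (participants without events still contribute observation time).
    """
    pids = list(followup_by_participant)
    if not pids:
        raise ValueError("mcf_estimate requires a non-empty roster")
    followup = np.array([followup_by_participant[p] for p in pids], dtype=float)
    ev_times, ev_pid_idx = [], []
    index = {p: i for i, p in enumerate(pids)}
    for pid, times in event_times_by_participant.items():
        if pid not in index:
            raise ValueError(f"participant {pid!r} has events but no follow-up")
        for t in times:
            if t > followup_by_participant[pid]:
                raise ValueError(
                    f"participant {pid!r}: event time {t} exceeds follow-up"
                )
            ev_times.append(float(t))
            ev_pid_idx.append(index[pid])
    n = len(pids)

    if not ev_times:
        empty = np.empty(0)
        return SurvivalCurve(
            times=empty, estimate=empty.copy(), variance=empty.copy(),
            ci_low=empty.copy(), ci_high=empty.copy(), kind="mcf", n=n,
            arm=arm, alpha=alpha,
        )

    ev_times = np.asarray(ev_times)
    ev_pid_idx = np.asarray(ev_pid_idx)
    distinct = np.unique(ev_times)

    z = stats.norm.ppf(1 - alpha / 2)
    mcf = np.empty_like(distinct)
    var = np.empty_like(distinct)
    running = 0.0
    resid = np.zeros(n)  # per-participant cumulative residuals
    for j, t in enumerate(distinct):
        at_risk = followup >= t
        y = at_risk.sum()
        d_i = np.bincount(ev_pid_idx[ev_times == t], minlength=n).astype(float)
        d = d_i.sum()
        m = d / y
        running += m
        mcf[j] = running
        resid += np.where(at_risk, (d_i - m) / y, 0.0)
        var[j] = np.sum(resid**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        se_rel = np.sqrt(var) / mcf
        lo = mcf * np.exp(-z * se_rel)
        hi = mcf * np.exp(z * se_rel)
    lo = np.where(mcf > 0, lo, 0.0)
    hi = np.where(mcf > 0, hi, 0.0)
    return SurvivalCurve(
        times=distinct, estimate=mcf, variance=var, ci_low=lo, ci_high=hi,
        kind="mcf", n=n, arm=arm, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Survival ratio
# ---------------------------------------------------------------------------


def _km_eval(event_times: np.ndarray, surv: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(event_times, grid, side="right")
    return np.concatenate([[1.0], surv])[idx]


def survival_ratio(
    records_arm1,
    records_arm2,
    *,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int,
    mode: str = "ratio",
    reference: str = "arm1",
    comparator: str = "arm2",
) -> SurvivalRatioCurve:
    """Ratio (or difference) of Kaplan-Meier estimates with bootstrap bands.

    The reference arm's survival is the numerator (first operand).  The curve
    is evaluated on the union of both arms' event-time grids; in ratio mode
    the grid is truncated once either arm's estimate reaches zero.  Bands are
    pointwise percentile intervals over ``n_boot`` resamples of participants
    with replacement within each arm; the seed is required so bands are
    bit-reproducible.  A degenerate resample in which every drawn participant
    is censored simply yields a flat survival of 1.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    t1, s1 = _coerce_records(records_arm1)
    t2, s2 = _coerce_records(records_arm2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both arms must be non-empty")

    e1, _, _, surv1, _ = _km_core(t1, s1)
    e2, _, _, surv2, _ = _km_core(t2, s2)
    grid = np.union1d(e1, e2)
    g1 = _km_eval(e1, surv1, grid)
    g2 = _km_eval(e2, surv2, grid)
    if mode == "ratio":
        keep = (g1 > 0) & (g2 > 0)
        grid, g1, g2 = grid[keep], g1[keep], g2[keep]
        stat = g1 / g2
    else:
        stat = g1 - g2

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, grid.size))
    n1, n2 = t1.size, t2.size
    for b in range(n_boot):
        i1 = rng.integers(0, n1, n1)
        i2 = rng.integers(0, n2, n2)
        be1, _, _, bs1, _ = _km_core(t1[i1], s1[i1])
        be2, _, _, bs2, _ = _km_core(t2[i2], s2[i2])
        bg1 = _km_eval(be1, bs1, grid)
        bg2 = _km_eval(be2, bs2, grid)
        if mode == "ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                boot[b] = np.where(bg2 > 0, bg1 / np.where(bg2 > 0, bg2, 1.0), np.inf)
        else:
            boot[b] = bg1 - bg2

    with np.errstate(invalid="ignore"):  # inf - inf inside percentile interp
        lo = np.percentile(boot, 100 * alpha / 2, axis=0)
        hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    # interpolating between two infinite order statistics yields NaN; the
    # correct limit is +inf (a resampled comparator arm ran out of survivors)
    lo = np.where(np.isnan(lo), np.inf, lo)
    hi = np.where(np.isnan(hi), np.inf, hi)
    null = 1.0 if mode == "ratio" else 0.0
    excludes = (lo > null) | (hi < null)
    return SurvivalRatioCurve(
        times=grid, ratio=stat, ci_low=lo, ci_high=hi, excludes_unity=excludes,
        mode=mode, reference=reference, comparator=comparator,
        n_boot=n_boot, seed=seed, alpha=alpha,
    )
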