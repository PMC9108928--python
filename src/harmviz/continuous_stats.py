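"""Summaries for continuous harm outcomes: per-visit location and spread,
kernel density estimation, and change-from-baseline scores.

Per-visit summaries can show means with standard deviations (the SD describes
the variability of individual values, deliberately not the standard error) or
medians with interquartile ranges; quantiles use linear interpolation of
order statistics (numpy's default, "type 7"), fixed for reproducibility.
Model-based summaries (e.g. mixed-model means with 95% CIs) are accepted as
pre-computed rows with ``statistic_kind="model_ci"`` rather than fitted here.

The density estimator uses a Gaussian kernel with Silverman's rule-of-thumb
bandwidth, 0.9 * min(SD, IQR/1.34) * n^(-1/5), and applies no boundary
correction — for non-negative outcomes such as eosinophil counts the
estimated density can therefore extend below zero, a known cosmetic
limitation of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialDataset

__all__ = [
    "DegenerateDataError",
    "DensityEstimate",
    "summarize_timepoints",
    "silverman_bandwidth",
    "kde",
    "change_scores",
]

MEAN_SD = "mean_sd"
MEDIAN_IQR = "median_iqr"
MODEL_CI = "model_ci"

SUMMARY_COLUMNS = [
    "arm", "visit_time", "n", "center", "spread_low", "spread_high", "statistic_kind",
]


class DegenerateDataError(ValueError):
    """All values identical: a density estimate is meaningless; show the raw
    points (rug/strip) instead."""


@dataclass
class DensityEstimate:
    """A kernel density estimate on an increasing grid of abscissae."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        """Trapezoid integral over the grid (~1 by construction)."""
        return float(np.trapezoid(self.density, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.grid, "density": self.density, "bandwidth": self.bandwidth}
        )


def summarize_timepoints(
    dataset: TrialDataset, outcome: str, statistic_kind: str = MEAN_SD
) -> pd.DataFrame:
    """Per-(arm, visit) location and spread for a continuous outcome.

    ``statistic_kind="mean_sd"`` gives mean with (mean - SD, mean + SD);
    ``"median_iqr"`` gives median with (Q1, Q3).  The returned ``n`` per
    visit feeds the participant-count table under the line graph.  With a
    single observation the spread collapses to the center.
    """
    if statistic_kind not in (MEAN_SD, MEDIAN_IQR):
        raise ValueError(
            f"statistic_kind must be '{MEAN_SD}' or '{MEDIAN_IQR}' "
            f"(model-based rows are supplied pre-computed as '{MODEL_CI}')"
        )
    meas = dataset.measurements[dataset.measurements["outcome"] == outcome]
    if meas.empty:
        raise KeyError(
            f"outcome {outcome!r} not present; available: "
            f"{sorted(dataset.measurements['outcome'].unique())}"
        )
    arm_of = dataset.arm_by_participant()
    meas = meas.assign(arm=lambda d: d["participant_id"].map(arm_of))
    rows = []
    for (arm, visit), grp in meas.groupby(["arm", "visit_time"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        n = v.size
        if statistic_kind == MEAN_SD:
            center = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
            lo, hi = center - sd, center + sd
        else:
            center = float(np.median(v))
            lo, hi = (float(q) for q in np.percentile(v, [25, 75]))
        rows.append((arm, float(visit), n, center, lo, hi, statistic_kind))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(SD, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * sigma * v.size ** (-1 / 5)


def kde(values, bandwidth_rule: str | float = "silverman", gridsize: int = 512) -> DensityEstimate:
    """Gaussian kernel density estimate of a continuous sample.

    ``bandwidth_rule`` is either ``"silverman"`` or an explicit positive
    bandwidth.  The grid spans the data plus three bandwidths each side, so
    the trapezoid integral of the density is 1 to well within 1%.

    Raises :class:`DegenerateDataError` when the sample has fewer than two
    distinct values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[0] == v[-1]:
        raise DegenerateDataError(
            "need at least two distinct values for a density estimate; "
            "display the raw points instead"
        )
    if bandwidth_rule == "silverman":
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth_rule)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(v[0] - 3 * h, v[-1] + 3 * h, gridsize)
    density = stats.norm.pdf((grid[:, None] - v[None, :]) / h).sum(axis=1) / (v.size * h)
    return DensityEstimate(grid=grid, density=density, bandwidth=h)


def change_scores(
    dataset: TrialDataset,
    outcome: str,
    mode: str = "to_maximum",
    at_time: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Change from baseline per participant: to a fixed visit or to the
    maximum post-baseline value.

    ``mode="to_time"`` needs ``at_time``; ``mode="to_maximum"`` uses the
    maximum over all post-baseline visits (when treatment stops before the
    last visit this still includes post-treatment visits — callers needing a
    narrower window should subset the measurements first).

    Returns ``(scores, excluded)``: scores has columns ``participant_id``,
    ``arm``, ``score``; excluded reports participants missing the baseline
    or target value.
    """
    if mode not in ("to_maximum", "to_time"):
        raise ValueError("mode must be 'to_maximum' or 'to_time'")
    if mode == "to_time" and at_time is None:
        raise ValueError("mode='to_time' requires at_time")
    meas = dataset.measurements[dataset.measurements["outcome"] == outcome]
    if meas.empty:
        raise KeyError(f"outcome {outcome!r} not present")
    if not (meas["visit_time"] == 0).any():
        raise ValueError(f"outcome {outcome!r} has no baseline (visit_time = 0) records")
    arm_of = dataset.arm_by_participant()
    rows, excluded = [], []
    for pid, grp in meas.groupby("participant_id"):
        base = grp[grp["visit_time"] == 0]
        if base.empty:
            excluded.append((pid, arm_of[pid], "no baseline value"))
            continue
        baseline = float(base["value"].iloc[0])
        if mode == "to_maximum":
            post = grp[grp["visit_time"] > 0]
            if post.empty:
                excluded.append((pid, arm_of[pid], "no post-baseline value"))
                continue
            target = float(post["value"].max())
        else:
            at = grp[grp["visit_time"] == at_time]
            if at.empty:
                excluded.append((pid, arm_of[pid], f"no value at visit_time {at_time}"))
                continue
            target = float(at["value"].iloc[0])
        rows.append((pid, arm_of[pid], target - baseline))
    scores = pd.DataFrame(rows, columns=["participant_id", "arm", "score"])
    excl = pd.DataFrame(excluded, columns=["participant_id", "arm", "reason"])
    return scores, excl
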