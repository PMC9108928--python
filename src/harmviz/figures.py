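"""The ten endorsed harm-outcome plots.

Every builder returns a :class:`FigureArtifact` bundling the matplotlib
figure with the *exact* summary table it displays (the statistics-module
output, unmodified), plus the resolved option record — so the numbers behind
a figure are always exportable and auditable.

Styling: the default palette is colour-blind safe (Okabe-Ito); with
``grayscale=True`` arms are distinguished by line style, marker and hatch
instead of colour, for the plots that are meant to survive grayscale
reproduction.  Figures are vector-first (SVG/PDF) with PNG fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import continuous_stats, decision
from .binary_stats import (
    RISK_DIFFERENCE,
    EffectEstimate,
    EventSummary,
    estimates_to_frame,
    summaries_to_frame,
)
from .data_model import TrialDataset
from .time_to_event import RiskTable, SurvivalCurve, SurvivalRatioCurve

__all__ = [
    "FigureArtifact",
    "plot_dot",
    "plot_stacked_severity",
    "plot_count_bars",
    "plot_km",
    "plot_mcf",
    "plot_survival_ratio",
    "plot_line",
    "plot_violin",
    "plot_kde",
    "plot_scatter_matrix",
]

# Okabe-Ito colour-blind-safe palette
_PALETTE = ["#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00", "#56B4E9"]
_LINESTYLES = ["-", "--", "-.", ":"]
_MARKERS = ["o", "s", "^", "D", "v", "P"]
_HATCHES = ["", "////", "....", "xxxx", "\\\\\\\\", "++++"]

_DEFAULTS = {
    "grayscale": False,
    "figsize": None,
    "title": None,
}


class FigureError(ValueError):
    """Inconsistent inputs to a figure builder."""


@dataclass
class FigureArtifact:
    """A rendered endorsed plot plus the summary table it displays."""

    kind: str
    figure: matplotlib.figure.Figure
    table: pd.DataFrame | dict[str, pd.DataFrame]
    options: dict

    def save(
        self,
        out_dir: str | Path,
        basename: str | None = None,
        formats: Sequence[str] = ("svg",),
    ) -> list[Path]:
        """Write the figure (one file per format) and companion CSV table(s)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        base = basename or self.kind.replace(" ", "-")
        written = []
        for fmt in formats:
            path = out / f"{base}.{fmt}"
            self.figure.savefig(path, format=fmt, bbox_inches="tight")
            written.append(path)
        tables = self.table if isinstance(self.table, dict) else {"table": self.table}
        for name, df in tables.items():
            path = out / f"{base}.{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        return written

    def close(self) -> None:
        plt.close(self.figure)


def _resolve(options: dict | None) -> dict:
    out = dict(_DEFAULTS)
    out.update(options or {})
    return out


def _arm_styles(arms: Sequence[str], grayscale: bool) -> dict[str, dict]:
    """Per-arm style records; in grayscale mode arms differ by line style,
    marker and hatch so no information rides on colour alone."""
    styles = {}
    for i, arm in enumerate(arms):
        styles[arm] = {
            "color": "black" if grayscale else _PALETTE[i % len(_PALETTE)],
            "linestyle": _LINESTYLES[i % len(_LINESTYLES)] if grayscale else "-",
            "marker": _MARKERS[i % len(_MARKERS)],
            "hatch": _HATCHES[i % len(_HATCHES)] if grayscale else "",
        }
    return styles


def _step_xy(times: np.ndarray, values: np.ndarray, start: float, xmax: float):
    x = np.concatenate([[0.0], times, [xmax]])
    y = np.concatenate([[start], values, [values[-1] if values.size else start]])
    return x, y


# ---------------------------------------------------------------------------
# Dot plot
# ---------------------------------------------------------------------------


def plot_dot(
    summaries: Sequence[EventSummary],
    estimates: Sequence[tuple[str, EffectEstimate]],
    options: dict | None = None,
    dropped: Sequence[str] = (),
) -> FigureArtifact:
    """Three-panel dot plot: absolute risks, comparative estimates, data table.

    ``estimates`` must already be display-ordered (highest point estimate at
    the top, via :func:`~harmviz.binary_stats.order_for_dot_plot`) and cover
    exactly the events in ``summaries``; double-zero events dropped from the
    comparative panel are footnoted.  The central panel uses a log10 axis for
    ratio measures with a reference line at the value of no difference.  The
    absolute panel's axis spans [0, 1.1 x max %] rather than the full 0-100
    scale, so rare events remain readable.
    """
    opts = _resolve(options)
    summaries = [s for s in summaries]
    sum_labels = {s.label for s in summaries}
    est_labels = {label for label, _ in estimates} | set(dropped)
    if sum_labels != est_labels:
        raise FigureError(
            f"summaries and estimates cover different events: "
            f"{sorted(sum_labels ^ est_labels)}"
        )
    order = [label for label, _ in estimates] + list(dropped)
    by_label = {s.label: s for s in summaries}
    arms = list(next(iter(summaries)).per_arm)
    styles = _arm_styles(arms, opts["grayscale"])
    table_panel = opts.get("table_panel", "right")

    n_rows = len(order)
    fig, axes = plt.subplots(
        1, 3,
        figsize=opts["figsize"] or (11, 1.0 + 0.45 * n_rows),
        sharey=True,
        gridspec_kw={"width_ratios": (2.2, 2.2, 1.8)},
    )
    y = np.arange(n_rows)
    ax_abs, ax_rel = axes[0], axes[1]
    ax_tab = axes[2] if table_panel == "right" else axes[1]
    if table_panel == "central":
        ax_rel = axes[2]

    # absolute panel
    max_pct = 0.0
    for arm in arms:
        pct = [by_label[label].per_arm[arm].percent for label in order]
        max_pct = max(max_pct, max(pct, default=0.0))
        ax_abs.scatter(pct, y, label=arm, marker=styles[arm]["marker"],
                       color=styles[arm]["color"], zorder=3)
    ax_abs.set_xlim(0, max(max_pct * 1.1, 1.0))
    ax_abs.set_yticks(y)
    ax_abs.set_yticklabels(order)
    ax_abs.invert_yaxis()
    ax_abs.set_xlabel("participants with ≥1 event (%)")
    ax_abs.legend(frameon=False, fontsize=8)

    # comparative panel
    est_map = dict(estimates)
    if estimates:
        measure = estimates[0][1].measure
        null = estimates[0][1].null_value
    else:
        measure, null = None, 1.0
    for i, label in enumerate(order):
        e = est_map.get(label)
        if e is None:
            continue
        ax_rel.plot([e.ci_low, e.ci_high], [i, i], color="black", lw=1)
        ax_rel.plot([e.point], [i], marker="o", color="black", ms=4)
    ax_rel.axvline(null, linestyle="--", color="gray", lw=1)
    if measure is not None and measure != RISK_DIFFERENCE:
        ax_rel.set_xscale("log", base=10)
    ax_rel.set_xlabel(measure or "")

    # data table panel
    ax_tab.set_axis_off()
    col_x = np.linspace(0.1, 0.9, len(arms))
    for j, arm in enumerate(arms):
        ax_tab.text(col_x[j], -0.8, f"{arm}\nn (events)", ha="center",
                    va="bottom", fontsize=8, fontweight="bold")
        for i, label in enumerate(order):
            c = by_label[label].per_arm[arm]
            ax_tab.text(col_x[j], i, f"{c.n_participants} ({c.n_events})",
                        ha="center", va="center", fontsize=8)
    if dropped:
        fig.text(0.01, 0.01,
                 "No comparative estimate (zero events in both arms): "
                 + ", ".join(dropped), fontsize=7)
    if opts["title"]:
        fig.suptitle(opts["title"])
    fig.tight_layout()

    table = {
        "events": summaries_to_frame(summaries),
        "effects": estimates_to_frame(estimates),
    }
    opts.update({"arm_styles": styles, "null_value": null, "measure": measure,
                 "dropped": list(dropped), "row_order": order})
    return FigureArtifact(decision.DOT_PLOT, fig, table, opts)


# ---------------------------------------------------------------------------
# Stacked bar chart (maximum severity)
# ---------------------------------------------------------------------------


def plot_stacked_severity(
    max_severity_table: pd.DataFrame,
    arm_sizes: Mapping[str, int],
    severity_scale: Sequence[str],
    options: dict | None = None,
) -> FigureArtifact:
    """Horizontal stacked bars of % participants by maximum event severity.

    One bar per (event, arm), arms directly adjacent per event; the most
    severe grade sits closest to the vertical axis, and each bar is labelled
    with its participant count.  The total bar length is the percentage of
    participants with at least one such event.
    """
    opts = _resolve(options)
    tab = max_severity_table
    label_col = next(c for c in ("group", "term") if c in tab.columns)
    arms = list(arm_sizes)
    # default event order: descending total frequency (dot-plot convention)
    totals = tab.groupby(label_col)["n"].sum().sort_values(ascending=False)
    order = opts.get("event_order") or list(totals.index)
    grades_desc = list(severity_scale)[::-1]  # most severe first (innermost)
    gray = opts["grayscale"]
    n_grades = len(severity_scale)
    if gray:
        shades = [str(0.15 + 0.7 * i / max(n_grades - 1, 1)) for i in range(n_grades)]
    else:
        cmap = matplotlib.colormaps["Reds"]
        shades = [cmap(0.9 - 0.6 * i / max(n_grades - 1, 1)) for i in range(n_grades)]

    fig, ax = plt.subplots(
        figsize=opts["figsize"] or (8, 1.0 + 0.5 * len(order) * len(arms))
    )
    bar_h = 0.8 / len(arms)
    segments = []
    for ei, event in enumerate(order):
        for ai, arm in enumerate(arms):
            ypos = ei + (ai - (len(arms) - 1) / 2) * bar_h
            left = 0.0
            total_n = 0
            for gi, grade in enumerate(grades_desc):
                rows = tab[(tab[label_col] == event) & (tab["arm"] == arm)
                           & (tab["severity"] == grade)]
                n = int(rows["n"].sum())
                pct = 100.0 * n / arm_sizes[arm]
                if n > 0:
                    ax.barh(ypos, pct, height=bar_h * 0.9, left=left,
                            color=shades[gi], edgecolor="black", linewidth=0.5,
                            hatch=_HATCHES[gi] if gray else "")
                segments.append((event, arm, grade, left, pct, n))
                left += pct
                total_n += n
            ax.text(left + 0.3, ypos, str(total_n), va="center", fontsize=8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order)
    ax.invert_yaxis()
    ax.set_xlabel("participants (%) by maximum severity")
    handles = [matplotlib.patches.Patch(facecolor=shades[i], edgecolor="black",
                                        hatch=_HATCHES[i] if gray else "",
                                        label=g)
               for i, g in enumerate(grades_desc)]
    ax.legend(handles=handles, frameon=False, fontsize=8, title="max severity")
    if opts["title"]:
        ax.set_title(opts["title"])
    fig.tight_layout()
    opts.update({
        "event_order": order,
        "segments": pd.DataFrame(
            segments, columns=["event", "arm", "severity", "left", "width", "n"]
        ),
    })
    return FigureArtifact(decision.STACKED_BAR_CHART, fig, tab, opts)


# ---------------------------------------------------------------------------
# Bar chart of event counts
# ---------------------------------------------------------------------------


def plot_count_bars(count_table: pd.DataFrame, options: dict | None = None) -> FigureArtifact:
    """Percentage of participants by number of events, per arm.

    Two arms are drawn side by side in one panel; with more arms each gets
    its own panel, stacked vertically with shared axes.
    """
    opts = _resolve(options)
    tab = count_table
    arms = list(dict.fromkeys(tab["arm"]))
    ks = sorted(tab["k"].unique())
    styles = _arm_styles(arms, opts["grayscale"])
    show_counts = opts.get("show_counts", False)

    def _bars(ax, arm, offset=0.0, width=0.8):
        sub = tab[tab["arm"] == arm].set_index("k")
        pct = [float(sub["percent"].get(k, 0.0)) for k in ks]
        ns = [int(sub["n"].get(k, 0)) for k in ks]
        xs = np.arange(len(ks)) + offset
        ax.bar(xs, pct, width=width, label=arm,
               color="white" if opts["grayscale"] else styles[arm]["color"],
               edgecolor="black", hatch=styles[arm]["hatch"])
        if show_counts:
            for x, p, n in zip(xs, pct, ns):
                ax.text(x, p + 0.5, str(n), ha="center", fontsize=7)

    if len(arms) <= 2:
        fig, ax = plt.subplots(figsize=opts["figsize"] or (7, 4))
        width = 0.8 / len(arms)
        for ai, arm in enumerate(arms):
            _bars(ax, arm, offset=(ai - (len(arms) - 1) / 2) * width, width=width * 0.95)
        ax.set_xticks(np.arange(len(ks)))
        ax.set_xticklabels([str(k) for k in ks])
        ax.set_xlabel("number of events per participant")
        ax.set_ylabel("participants (%)")
        ax.legend(frameon=False)
        axes = [ax]
    else:
        fig, axes = plt.subplots(
            len(arms), 1, sharex=True, sharey=True,
            figsize=opts["figsize"] or (7, 2.2 * len(arms)),
        )
        for ax, arm in zip(axes, arms):
            _bars(ax, arm)
            ax.set_ylabel("participants (%)")
            ax.set_title(arm, fontsize=9, loc="left")
        axes[-1].set_xticks(np.arange(len(ks)))
        axes[-1].set_xticklabels([str(k) for k in ks])
        axes[-1].set_xlabel("number of events per participant")
        axes = list(axes)
    if opts["title"]:
        fig.suptitle(opts["title"])
    fig.tight_layout()
    opts.update({"arm_styles": styles, "n_panels": len(axes)})
    return FigureArtifact(decision.BAR_CHART, fig, tab, opts)


# ---------------------------------------------------------------------------
# Kaplan-Meier / MCF with extended risk table
# ---------------------------------------------------------------------------


def _render_risk_table(ax, risk_table: RiskTable, xlim) -> None:
    ax.set_xlim(*xlim)
    ax.set_ylim(-0.5, None)
    ax.set_axis_off()
    rows = []
    for arm in risk_table.arms:
        sub = risk_table.for_arm(arm)
        rows.append((f"{arm} at risk", sub["at_risk"]))
        rows.append(("  cum. censored", sub["cum_censored"]))
        rows.append(("  cum. events", sub["cum_events"]))
    n_rows = len(rows)
    ax.set_ylim(n_rows - 0.5, -0.5)
    for ri, (label, vals) in enumerate(rows):
        ax.text(xlim[0] - 0.01 * (xlim[1] - xlim[0]), ri, label,
                ha="right", va="center", fontsize=7)
        for t, v in zip(risk_table.timepoints, vals):
            ax.text(t, ri, str(int(v)), ha="center", va="center", fontsize=7)


def _plot_step_curves(
    kind: str,
    curves: Sequence[SurvivalCurve],
    risk_table: RiskTable,
    options: dict | None,
) -> FigureArtifact:
    opts = _resolve(options)
    curve_arms = [c.arm for c in curves]
    if set(curve_arms) != set(risk_table.arms):
        raise FigureError(
            f"curves ({sorted(map(str, curve_arms))}) and risk table "
            f"({sorted(map(str, risk_table.arms))}) cover different arms"
        )
    reversed_axis = opts.get("reversed_axis", False) and kind == "km"
    show_bands = opts.get("show_bands", True)
    styles = _arm_styles(curve_arms, opts["grayscale"])
    xmax = float(risk_table.timepoints[-1])
    n_table_rows = 3 * len(curve_arms)
    fig, (ax, ax_tab) = plt.subplots(
        2, 1, figsize=opts["figsize"] or (8, 5.0 + 0.18 * n_table_rows),
        gridspec_kw={"height_ratios": (4, 0.32 * n_table_rows)},
        sharex=False,
    )
    for c in curves:
        st = styles[c.arm]
        x, y = _step_xy(c.times, c.estimate, c.start_value, xmax)
        _, lo = _step_xy(c.times, c.ci_low, c.start_value, xmax)
        _, hi = _step_xy(c.times, c.ci_high, c.start_value, xmax)
        if reversed_axis:
            y, lo, hi = 1 - y, 1 - hi, 1 - lo
        ax.step(x, y, where="post", label=str(c.arm),
                color=st["color"], linestyle=st["linestyle"])
        if show_bands:
            ax.fill_between(x, lo, hi, step="post", alpha=0.2,
                            color=st["color"],
                            hatch=st["hatch"] if opts["grayscale"] else None)
    ax.set_xlim(0, xmax)
    if kind == "km":
        ax.set_ylim(0, 1.02)
        ax.set_ylabel(
            "cumulative proportion with event" if reversed_axis
            else "proportion event-free"
        )
    else:
        ax.set_ylim(bottom=0)
        ax.set_ylabel("mean cumulative events per participant")
    ax.set_xlabel("days since randomisation")
    ax.legend(frameon=False)
    if opts["title"]:
        ax.set_title(opts["title"])
    _render_risk_table(ax_tab, risk_table, (0, xmax))
    fig.tight_layout()
    table = {
        "curves": pd.concat([c.to_frame() for c in curves], ignore_index=True),
        "risk_table": risk_table.table,
    }
    opts.update({"arm_styles": styles, "reversed_axis": reversed_axis,
                 "show_bands": show_bands})
    name = decision.KAPLAN_MEIER_PLOT if kind == "km" else decision.MCF_PLOT
    return FigureArtifact(name, fig, table, opts)


def plot_km(
    curves: Sequence[SurvivalCurve],
    risk_table: RiskTable,
    options: dict | None = None,
) -> FigureArtifact:
    """Kaplan-Meier step curves with within-arm bands and the extended
    at-risk table beneath, aligned to the time axis.

    Option ``reversed_axis=True`` plots the cumulative proportion *with* the
    event (1 - S), which reads better for rare events.
    """
    if any(c.kind != "km" for c in curves):
        raise FigureError("plot_km expects Kaplan-Meier curves")
    return _plot_step_curves("km", curves, risk_table, options)


def plot_mcf(
    curves: Sequence[SurvivalCurve],
    risk_table: RiskTable,
    options: dict | None = None,
) -> FigureArtifact:
    """Mean cumulative function curves with the extended risk table beneath.

    Option ``show_bands=False`` suppresses the confidence bands, which keeps
    multi-arm displays readable.
    """
    if any(c.kind != "mcf" for c in curves):
        raise FigureError("plot_mcf expects mean-cumulative-function curves")
    return _plot_step_curves("mcf", curves, risk_table, options)


# ---------------------------------------------------------------------------
# Survival ratio plot
# ---------------------------------------------------------------------------


def plot_survival_ratio(
    ratio_curve: SurvivalRatioCurve, options: dict | None = None
) -> FigureArtifact:
    """Survival ratio (or difference) over time with pointwise bootstrap
    bands, a reference line at the null, and a bottom indicator bar that
    changes from green to red (hatched, for grayscale) wherever the band
    excludes the null."""
    opts = _resolve(options)
    rc = ratio_curve
    xmax = float(rc.times[-1]) if rc.times.size else 1.0
    fig, (ax, ax_bar) = plt.subplots(
        2, 1, figsize=opts["figsize"] or (8, 5),
        gridspec_kw={"height_ratios": (10, 0.7)}, sharex=True,
    )
    x, y = _step_xy(rc.times, rc.ratio, rc.ratio[0] if rc.ratio.size else rc.null_value, xmax)
    _, lo = _step_xy(rc.times, rc.ci_low, rc.ci_low[0] if rc.ci_low.size else rc.null_value, xmax)
    _, hi = _step_xy(rc.times, rc.ci_high, rc.ci_high[0] if rc.ci_high.size else rc.null_value, xmax)
    finite_hi = np.where(np.isfinite(hi), hi, np.nan)
    ax.step(x, y, where="post", color="black")
    ax.fill_between(x, lo, finite_hi, step="post", alpha=0.2, color="gray")
    ax.axhline(rc.null_value, linestyle="--", color="gray", lw=1)
    label = "survival ratio" if rc.mode == "ratio" else "survival difference"
    ax.set_ylabel(f"{label} ({rc.reference} / {rc.comparator})"
                  if rc.mode == "ratio"
                  else f"{label} ({rc.reference} - {rc.comparator})")
    if opts["title"]:
        ax.set_title(opts["title"])

    # indicator bar: contiguous segments of equal exclusion status
    segments = []
    times = np.concatenate([rc.times, [xmax]]) if rc.times.size else np.array([0.0, xmax])
    flags = rc.excludes_unity
    start_idx = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start_idx]:
            segments.append((float(times[start_idx]), float(times[i]), bool(flags[start_idx])))
            start_idx = i
    gray = opts["grayscale"]
    for t0, t1, excl in segments:
        color = ("black" if gray else "red") if excl else ("0.8" if gray else "green")
        ax_bar.axvspan(t0, t1, color=color, hatch="////" if excl else None)
    ax_bar.set_yticks([])
    ax_bar.set_xlim(0, xmax)
    ax_bar.set_xlabel("days since randomisation")
    fig.tight_layout()
    opts.update({"indicator_segments": segments, "null_value": rc.null_value})
    return FigureArtifact(decision.SURVIVAL_RATIO_PLOT, fig, rc.to_frame(), opts)


# ---------------------------------------------------------------------------
# Line graph
# ---------------------------------------------------------------------------


def plot_line(
    summaries: pd.DataFrame,
    normal_range: tuple[float | None, float | None] = (None, None),
    options: dict | None = None,
) -> FigureArtifact:
    """Per-visit centers with vertical spread bars, connected per arm, with
    normal-limit reference lines and a participant-count table beneath.

    ``summaries`` is the frame from
    :func:`~harmviz.continuous_stats.summarize_timepoints` (or pre-computed
    model-based rows with ``statistic_kind="model_ci"``).  A missing normal
    range draws no reference lines and logs a warning.
    """
    opts = _resolve(options)
    arms = list(dict.fromkeys(summaries["arm"]))
    styles = _arm_styles(arms, opts["grayscale"])
    visits = sorted(summaries["visit_time"].unique())
    fig, (ax, ax_tab) = plt.subplots(
        2, 1, figsize=opts["figsize"] or (8, 5.5),
        gridspec_kw={"height_ratios": (5, 0.4 * len(arms))}, sharex=False,
    )
    for arm in arms:
        sub = summaries[summaries["arm"] == arm].sort_values("visit_time")
        st = styles[arm]
        err = np.vstack([
            sub["center"] - sub["spread_low"],
            sub["spread_high"] - sub["center"],
        ])
        ax.errorbar(sub["visit_time"], sub["center"], yerr=err, label=arm,
                    color=st["color"], linestyle=st["linestyle"],
                    marker=st["marker"], capsize=3, ms=4)
    lower, upper = normal_range
    if lower is None and upper is None:
        warnings.warn("no normal range configured: reference lines omitted")
    for limit in (lower, upper):
        if limit is not None:
            ax.axhline(limit, linestyle=":", color="gray", lw=1)
    ax.set_xlabel("visit time (days)")
    ax.set_ylabel(opts.get("ylabel", "value"))
    ax.legend(frameon=False)
    if opts["title"]:
        ax.set_title(opts["title"])
    # participant-count table
    ax_tab.set_axis_off()
    x0, x1 = ax.get_xlim()
    ax_tab.set_xlim(x0, x1)
    ax_tab.set_ylim(len(arms) - 0.5, -0.5)
    for ri, arm in enumerate(arms):
        sub = summaries[summaries["arm"] == arm].set_index("visit_time")
        ax_tab.text(x0 - 0.01 * (x1 - x0), ri, f"{arm} n", ha="right",
                    va="center", fontsize=7)
        for v in visits:
            if v in sub.index:
                ax_tab.text(v, ri, str(int(sub.loc[v, "n"])), ha="center",
                            va="center", fontsize=7)
    fig.tight_layout()
    opts.update({"arm_styles": styles, "normal_range": (lower, upper)})
    return FigureArtifact(decision.LINE_GRAPH, fig, summaries, opts)


# ---------------------------------------------------------------------------
# Violin plot
# ---------------------------------------------------------------------------


def plot_violin(
    dataset: TrialDataset, outcome: str, options: dict | None = None
) -> FigureArtifact:
    """Mirrored kernel densities per (visit, arm) with a hollow median
    circle, a narrow IQR box and min/max whiskers, plus normal-limit lines.

    Option ``half_violin=True`` draws the density on one side only, which
    improves clarity; cells with fewer than two distinct values are drawn as
    a point with whiskers only.  The companion table is the median/IQR
    per-visit summary.
    """
    opts = _resolve(options)
    summary = continuous_stats.summarize_timepoints(
        dataset, outcome, continuous_stats.MEDIAN_IQR
    )
    meas = dataset.measurements[dataset.measurements["outcome"] == outcome]
    arm_of = dataset.arm_by_participant()
    meas = meas.assign(arm=lambda d: d["participant_id"].map(arm_of))
    arms = [a for a in dataset.arms if a in set(meas["arm"])]
    visits = sorted(meas["visit_time"].unique())
    styles = _arm_styles(arms, opts["grayscale"])
    half = opts.get("half_violin", False)
    spacing = 1.0
    offset = spacing / (len(arms) + 1)
    max_halfwidth = offset * 0.42

    fig, ax = plt.subplots(figsize=opts["figsize"] or (1.5 + 1.6 * len(visits), 4.5))
    for vi, visit in enumerate(visits):
        for ai, arm in enumerate(arms):
            vals = meas[(meas["visit_time"] == visit) & (meas["arm"] == arm)][
                "value"
            ].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            xc = vi * spacing + (ai - (len(arms) - 1) / 2) * offset
            st = styles[arm]
            try:
                dens = continuous_stats.kde(vals)
                w = dens.density / dens.density.max() * max_halfwidth
                if half:
                    ax.fill_betweenx(dens.grid, xc, xc + w, alpha=0.4,
                                     color=st["color"], linewidth=0.5)
                else:
                    ax.fill_betweenx(dens.grid, xc - w, xc + w, alpha=0.4,
                                     color=st["color"], linewidth=0.5)
            except continuous_stats.DegenerateDataError:
                pass  # degenerate cell: point + whisker only
            med = float(np.median(vals))
            q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
            ax.plot([xc, xc], [vals.min(), vals.max()], color=st["color"],
                    lw=0.8, linestyle=st["linestyle"])
            ax.add_patch(matplotlib.patches.Rectangle(
                (xc - max_halfwidth * 0.12, q1), max_halfwidth * 0.24, q3 - q1,
                facecolor=st["color"], edgecolor="black", lw=0.5, zorder=3))
            ax.plot([xc], [med], marker="o", mfc="white", mec="black",
                    ms=5, zorder=4)
    lower, upper = dataset.normal_range(outcome)
    for limit in (lower, upper):
        if limit is not None:
            ax.axhline(limit, linestyle="--", color="gray", lw=1)
    ax.set_xticks([vi * spacing for vi in range(len(visits))])
    ax.set_xticklabels([str(v) for v in visits])
    ax.set_xlabel("visit time (days)")
    ax.set_ylabel(outcome)
    handles = [matplotlib.lines.Line2D([], [], color=styles[a]["color"],
                                       linestyle=styles[a]["linestyle"], label=a)
               for a in arms]
    ax.legend(handles=handles, frameon=False, fontsize=8)
    if opts["title"]:
        ax.set_title(opts["title"])
    fig.tight_layout()
    opts.update({"arm_styles": styles, "half_violin": half,
                 "normal_range": (lower, upper)})
    return FigureArtifact(decision.VIOLIN_PLOT, fig, summary, opts)


# ---------------------------------------------------------------------------
# Kernel density plot
# ---------------------------------------------------------------------------


def plot_kde(
    values_by_arm: Mapping[str, Sequence[float]],
    normal_range: tuple[float | None, float | None] = (None, None),
    options: dict | None = None,
) -> FigureArtifact:
    """Overlaid per-arm kernel densities of a continuous outcome (raw values
    or change scores), with vertical reference lines at the normal limits."""
    opts = _resolve(options)
    arms = list(values_by_arm)
    styles = _arm_styles(arms, opts["grayscale"])
    fig, ax = plt.subplots(figsize=opts["figsize"] or (7, 4.5))
    frames = []
    for arm in arms:
        dens = continuous_stats.kde(
            values_by_arm[arm], opts.get("bandwidth_rule", "silverman")
        )
        st = styles[arm]
        ax.plot(dens.grid, dens.density, label=arm, color=st["color"],
                linestyle=st["linestyle"])
        frames.append(dens.to_frame().assign(arm=arm))
    lower, upper = normal_range
    for limit in (lower, upper):
        if limit is not None:
            ax.axvline(limit, linestyle="--", color="gray", lw=1)
    ax.set_xlabel(opts.get("xlabel", "value"))
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    if opts["title"]:
        ax.set_title(opts["title"])
    fig.tight_layout()
    table = pd.concat(frames, ignore_index=True)
    opts.update({"arm_styles": styles, "normal_range": (lower, upper)})
    return FigureArtifact(decision.KERNEL_DENSITY_PLOT, fig, table, opts)


# ---------------------------------------------------------------------------
# Scatterplot matrix
# ---------------------------------------------------------------------------


def plot_scatter_matrix(
    baseline_max_tables: Mapping[str, pd.DataFrame],
    ranges: Mapping[str, tuple[float | None, float | None]],
    options: dict | None = None,
) -> FigureArtifact:
    """One panel per outcome: baseline (x) versus maximum post-baseline value
    (y) per participant, with dashed normal-limit lines forming quadrants,
    per-arm symbols with transparency, an optional identity diagonal, and
    participant-id labels on points outside the normal limits."""
    opts = _resolve(options)
    outcomes = list(baseline_max_tables)
    n = len(outcomes)
    ncols = min(n, 3)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=opts["figsize"] or (4 * ncols, 3.6 * nrows),
        squeeze=False,
    )
    all_arms = list(dict.fromkeys(
        arm for tab in baseline_max_tables.values() for arm in tab["arm"]
    ))
    styles = _arm_styles(all_arms, opts["grayscale"])
    labelled: dict[str, list] = {}
    for idx, outcome in enumerate(outcomes):
        ax = axes[idx // ncols][idx % ncols]
        tab = baseline_max_tables[outcome]
        lower, upper = ranges.get(outcome, (None, None))
        for arm in all_arms:
            sub = tab[tab["arm"] == arm]
            ax.scatter(sub["baseline"], sub["maximum"], label=arm, alpha=0.6,
                       marker=styles[arm]["marker"], color=styles[arm]["color"])
        for limit in (lower, upper):
            if limit is not None:
                ax.axvline(limit, linestyle="--", color="gray", lw=1)
                ax.axhline(limit, linestyle="--", color="gray", lw=1)
        if opts.get("identity_line", True):
            lo = min(tab["baseline"].min(), tab["maximum"].min())
            hi = max(tab["baseline"].max(), tab["maximum"].max())
            ax.plot([lo, hi], [lo, hi], color="0.7", lw=0.8, zorder=0)

        def _outside(v):
            return (lower is not None and v < lower) or (
                upper is not None and v > upper
            )

        outliers = []
        for _, rec in tab.iterrows():
            if _outside(rec["baseline"]) or _outside(rec["maximum"]):
                ax.annotate(str(rec["participant_id"]),
                            (rec["baseline"], rec["maximum"]),
                            fontsize=7, xytext=(3, 3), textcoords="offset points")
                outliers.append(rec["participant_id"])
        labelled[outcome] = outliers
        ax.set_title(outcome, fontsize=9)
        ax.set_xlabel("baseline")
        ax.set_ylabel("maximum over follow-up")
    for idx in range(n, nrows * ncols):
        axes[idx // ncols][idx % ncols].set_axis_off()
    axes[0][0].legend(frameon=False, fontsize=8)
    if opts["title"]:
        fig.suptitle(opts["title"])
    fig.tight_layout()
    opts.update({"arm_styles": styles, "labelled": labelled, "n_panels": n})
    return FigureArtifact(
        decision.SCATTERPLOT_MATRIX, fig, dict(baseline_max_tables), opts
    )
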