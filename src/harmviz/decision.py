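"""Executable decision tree for choosing a harm-outcome plot.

Maps the characteristics of the outcome to be displayed — its type (binary,
count, continuous, time-to-event), whether one or many outcomes are shown,
and flags for severity interest, recurrence, time structure and
distributional shape — to the endorsed plot(s).  Some combinations have no
suitable endorsed plot (notably multiple time-to-event outcomes); these
return an empty list with an explicit warning rather than a guess.

The recommendation is advisory: the trial team must ultimately decide the
most appropriate visualisations for their data and objectives, and a
combination of plots is often needed (e.g. a Kaplan-Meier plot alongside the
survival ratio plot for a prespecified event, plus a dot plot for the overall
harm profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DOT_PLOT",
    "STACKED_BAR_CHART",
    "BAR_CHART",
    "KAPLAN_MEIER_PLOT",
    "MCF_PLOT",
    "SURVIVAL_RATIO_PLOT",
    "LINE_GRAPH",
    "VIOLIN_PLOT",
    "KERNEL_DENSITY_PLOT",
    "SCATTERPLOT_MATRIX",
    "ENDORSED_PLOTS",
    "OutcomeSpec",
    "PlotRecommendation",
    "recommend",
]

DOT_PLOT = "dot plot"
STACKED_BAR_CHART = "stacked bar chart"
BAR_CHART = "bar chart"
KAPLAN_MEIER_PLOT = "Kaplan-Meier plot"
MCF_PLOT = "mean cumulative function plot"
SURVIVAL_RATIO_PLOT = "survival ratio plot"
LINE_GRAPH = "line graph"
VIOLIN_PLOT = "violin plot"
KERNEL_DENSITY_PLOT = "kernel density plot"
SCATTERPLOT_MATRIX = "scatterplot matrix"

#: The ten endorsed plot names.
ENDORSED_PLOTS = frozenset(
    {
        DOT_PLOT,
        STACKED_BAR_CHART,
        BAR_CHART,
        KAPLAN_MEIER_PLOT,
        MCF_PLOT,
        SURVIVAL_RATIO_PLOT,
        LINE_GRAPH,
        VIOLIN_PLOT,
        KERNEL_DENSITY_PLOT,
        SCATTERPLOT_MATRIX,
    }
)

OUTCOME_TYPES = ("binary", "count", "continuous", "time_to_event")
MULTIPLICITIES = ("single", "multiple")
TIME_STRUCTURES = ("single_timepoint", "repeated")

_CAVEAT = (
    "Recommendations are advisory: the trial team must decide the most "
    "appropriate visualisation(s) for their data and objectives."
)


@dataclass(frozen=True)
class OutcomeSpec:
    """Characteristics of the outcome(s) to be displayed.

    ``recurrent`` is meaningful only for binary/count/time-to-event
    outcomes; ``time_structure`` and ``distribution_normalish`` only for
    continuous ones.
    """

    outcome_type: str
    multiplicity: str = "single"
    severity_of_interest: bool = False
    recurrent: bool = False
    time_structure: str | None = None
    distribution_normalish: bool = True

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise ValueError(f"outcome_type must be one of {OUTCOME_TYPES}")
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"multiplicity must be one of {MULTIPLICITIES}")
        if self.recurrent and self.outcome_type == "continuous":
            raise ValueError("recurrent is only meaningful for event-type outcomes")
        if self.time_structure is not None:
            if self.outcome_type != "continuous":
                raise ValueError("time_structure applies only to continuous outcomes")
            if self.time_structure not in TIME_STRUCTURES:
                raise ValueError(f"time_structure must be one of {TIME_STRUCTURES}")
        if self.outcome_type == "continuous" and self.multiplicity == "single" and self.time_structure is None:
            raise ValueError(
                "a single continuous outcome needs time_structure "
                "('single_timepoint' or 'repeated')"
            )


@dataclass(frozen=True)
class PlotRecommendation:
    """Recommended endorsed plot name(s), possibly empty, with a rationale."""

    plots: tuple[str, ...]
    note: str

    def __post_init__(self) -> None:
        unknown = set(self.plots) - ENDORSED_PLOTS
        if unknown:
            raise ValueError(f"not endorsed plot names: {sorted(unknown)}")


def recommend(spec: OutcomeSpec) -> PlotRecommendation:
    """Recommend endorsed plot(s) for the given outcome characteristics.

    Total over all valid specs: every consistent combination yields either a
    non-empty plot list or an explicit no-suitable-plot warning.
    """
    if spec.outcome_type == "time_to_event":
        if spec.multiplicity == "multiple":
            return PlotRecommendation(
                (),
                "No suitable plot exists for displaying multiple time-to-event "
                "outcomes simultaneously; consider separate Kaplan-Meier plots "
                "for a limited number of prespecified events. " + _CAVEAT,
            )
        if spec.recurrent:
            return PlotRecommendation(
                (MCF_PLOT,),
                "A single recurrent time-to-event outcome: plot the mean "
                "cumulative number of events per participant over time. " + _CAVEAT,
            )
        return PlotRecommendation(
            (KAPLAN_MEIER_PLOT, SURVIVAL_RATIO_PLOT),
            "A single time-to-event outcome: the Kaplan-Meier plot (with the "
            "extended risk table) shows within-group estimates; present it "
            "alongside the survival ratio plot for the direct between-group "
            "comparison. " + _CAVEAT,
        )

    if spec.outcome_type == "count" or (
        spec.outcome_type == "binary" and spec.recurrent
    ):
        return PlotRecommendation(
            (BAR_CHART,),
            "A count (recurrent) outcome: bar chart of the percentage of "
            "participants by number of events per arm; the mean cumulative "
            "function plot additionally incorporates time. " + _CAVEAT,
        )

    if spec.outcome_type == "binary":
        if spec.multiplicity == "multiple":
            if spec.severity_of_interest:
                return PlotRecommendation(
                    (STACKED_BAR_CHART,),
                    "Multiple binary outcomes with severity ratings: stacked "
                    "bar chart by maximum severity. " + _CAVEAT,
                )
            return PlotRecommendation(
                (DOT_PLOT,),
                "Multiple binary outcomes: dot plot of absolute and relative "
                "summaries with the data table. " + _CAVEAT,
            )
        return PlotRecommendation(
            (),
            "A single binary outcome at a fixed horizon is best reported "
            "numerically; when onset times are recorded, recast it as "
            "time-to-event (Kaplan-Meier plot and survival ratio plot). "
            + _CAVEAT,
        )

    # continuous
    if spec.multiplicity == "multiple":
        return PlotRecommendation(
            (SCATTERPLOT_MATRIX,),
            "Multiple continuous outcomes: scatterplot matrix of baseline "
            "versus maximum values with normal-limit quadrants. " + _CAVEAT,
        )
    if spec.time_structure == "repeated":
        if spec.distribution_normalish:
            return PlotRecommendation(
                (LINE_GRAPH,),
                "A single continuous outcome repeated over time: line graph of "
                "per-visit summaries with normal-limit reference lines; the "
                "violin plot is an alternative when the distribution itself is "
                "of interest. " + _CAVEAT,
            )
        return PlotRecommendation(
            (VIOLIN_PLOT,),
            "A single continuous outcome repeated over time with a non-normal "
            "distribution (or interest in exploring the distribution): violin "
            "plot; the line graph of medians/IQRs is an alternative. " + _CAVEAT,
        )
    return PlotRecommendation(
        (KERNEL_DENSITY_PLOT,),
        "A single continuous outcome at a single time point: kernel density "
        "plot by arm with normal-limit reference lines. " + _CAVEAT,
    )
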