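"""Participant-level trial data structures and derived per-participant views.

The package works from four delimited-text tables (CSV, UTF-8, header row):

``roster``
    one row per randomised participant: ``participant_id``, ``arm``,
    ``followup_days`` (days from randomisation to end of observation).
``events``
    one row per adverse-event occurrence: ``participant_id``, ``term``,
    ``group`` (body system), ``severity``, ``onset_day``.  Recurrent events
    are simply repeated rows.
``measurements``
    one row per laboratory/continuous observation: ``participant_id``,
    ``outcome``, ``visit_time``, ``value``.  ``visit_time == 0`` is baseline.
``ranges``
    per-outcome normal limits: ``outcome``, ``lower``, ``upper``, ``units``.

Times are in days since randomisation (t = 0 at randomisation); events on the
same day as censoring count as events.  The denominator for all percentages is
the roster as supplied (the safety population).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_SEVERITY_SCALE",
    "ANY_EVENT",
    "TrialValidationError",
    "SelectorError",
    "TrialDataset",
    "read_trial",
    "read_config",
    "write_trial",
    "derive_first_event_times",
    "derive_max_severity",
    "derive_event_counts",
    "derive_baseline_max",
]

#: Default ordinal severity scale, least to most severe.
DEFAULT_SEVERITY_SCALE: tuple[str, ...] = ("mild", "moderate", "severe")

#: Selector meaning "any adverse event, regardless of term or group".
ANY_EVENT = "any"

#: Grouping label substituted when the body-system column is missing/empty.
OTHER_GROUP = "Other"

ROSTER_COLUMNS = ("participant_id", "arm", "followup_days")
EVENT_COLUMNS = ("participant_id", "term", "group", "severity", "onset_day")
MEASUREMENT_COLUMNS = ("participant_id", "outcome", "visit_time", "value")
RANGE_COLUMNS = ("outcome", "lower", "upper", "units")


class TrialValidationError(ValueError):
    """A typed invariant of the trial data was violated (row-addressed)."""


class SelectorError(KeyError):
    """An event selector matched no known term or group."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TrialValidationError(
            f"{table} table is missing required column(s): {', '.join(missing)}"
        )


@dataclass
class TrialDataset:
    """One trial's roster, adverse events, lab measurements and normal ranges.

    All statistics and figure builders consume this container.  Construct it
    with :func:`read_trial` (from CSV files) or :meth:`from_frames` (from
    in-memory DataFrames); both validate every invariant.
    """

    roster: pd.DataFrame
    events: pd.DataFrame
    measurements: pd.DataFrame
    ranges: pd.DataFrame
    severity_scale: tuple[str, ...] = DEFAULT_SEVERITY_SCALE

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        roster: pd.DataFrame,
        events: pd.DataFrame | None = None,
        measurements: pd.DataFrame | None = None,
        ranges: pd.DataFrame | None = None,
        severity_scale: Sequence[str] = DEFAULT_SEVERITY_SCALE,
    ) -> "TrialDataset":
        if events is None:
            events = pd.DataFrame(columns=list(EVENT_COLUMNS))
        if measurements is None:
            measurements = pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
        if ranges is None:
            ranges = pd.DataFrame(columns=list(RANGE_COLUMNS))
        ds = cls(
            roster=roster.reset_index(drop=True).copy(),
            events=events.reset_index(drop=True).copy(),
            measurements=measurements.reset_index(drop=True).copy(),
            ranges=ranges.reset_index(drop=True).copy(),
            severity_scale=tuple(severity_scale),
        )
        ds.validate()
        return ds

    def validate(self) -> None:
        """Check every typed invariant; raise :class:`TrialValidationError`."""
        _require_columns(self.roster, ROSTER_COLUMNS, "roster")
        _require_columns(self.events, EVENT_COLUMNS[:2] + EVENT_COLUMNS[3:], "events")
        _require_columns(self.measurements, MEASUREMENT_COLUMNS, "measurements")
        _require_columns(self.ranges, RANGE_COLUMNS[:3], "ranges")

        if len(set(self.severity_scale)) != len(self.severity_scale):
            raise TrialValidationError("severity scale contains duplicate grades")

        dup = self.roster["participant_id"][self.roster["participant_id"].duplicated()]
        if not dup.empty:
            row = dup.index[0]
            raise TrialValidationError(
                f"roster row {row}: duplicate participant_id {dup.iloc[0]!r}"
            )
        if self.roster["arm"].isna().any():
            row = int(self.roster["arm"].isna().idxmax())
            raise TrialValidationError(f"roster row {row}: missing arm label")
        bad_fu = self.roster.index[
            self.roster["followup_days"].isna() | (self.roster["followup_days"] < 0)
        ]
        if len(bad_fu):
            raise TrialValidationError(
                f"roster row {bad_fu[0]}: followup_days must be a non-negative number"
            )

        # events: fill missing grouping, then row-level checks
        if "group" not in self.events.columns:
            self.events["group"] = OTHER_GROUP
        self.events["group"] = (
            self.events["group"].replace("", np.nan).fillna(OTHER_GROUP)
        )
        known = set(self.roster["participant_id"])
        followup = self.followup_by_participant()
        scale = set(self.severity_scale)
        for row, rec in self.events.iterrows():
            pid = rec["participant_id"]
            if pid not in known:
                raise TrialValidationError(
                    f"events row {row}: participant {pid!r} absent from roster"
                )
            if rec["severity"] not in scale:
                raise TrialValidationError(
                    f"events row {row}: severity {rec['severity']!r} is not in the "
                    f"configured scale {list(self.severity_scale)}"
                )
            onset = rec["onset_day"]
            if pd.isna(onset) or onset < 0:
                raise TrialValidationError(
                    f"events row {row}: onset_day must be a non-negative number"
                )
            if onset > followup[pid]:
                raise TrialValidationError(
                    f"events row {row}: onset_day {onset} exceeds participant "
                    f"{pid!r}'s followup_days {followup[pid]}"
                )

        if not self.measurements.empty:
            unknown = ~self.measurements["participant_id"].isin(known)
            if unknown.any():
                row = int(unknown.idxmax())
                pid = self.measurements.loc[row, "participant_id"]
                raise TrialValidationError(
                    f"measurements row {row}: participant {pid!r} absent from roster"
                )
            key = ["participant_id", "outcome", "visit_time"]
            dupm = self.measurements.duplicated(subset=key)
            if dupm.any():
                row = int(dupm.idxmax())
                raise TrialValidationError(
                    f"measurements row {row}: duplicate (participant, outcome, "
                    "visit_time) record"
                )

        if not self.ranges.empty:
            both = self.ranges.dropna(subset=["lower", "upper"])
            bad = both.index[both["lower"] >= both["upper"]]
            if len(bad):
                raise TrialValidationError(
                    f"ranges row {bad[0]}: lower limit must be below upper limit"
                )

    # -- convenience views -------------------------------------------------

    @property
    def arms(self) -> list[str]:
        """Arm labels in roster order of first appearance."""
        return list(dict.fromkeys(self.roster["arm"]))

    def arm_sizes(self) -> dict[str, int]:
        return self.roster["arm"].value_counts().reindex(self.arms).astype(int).to_dict()

    def followup_by_participant(self) -> dict:
        return dict(zip(self.roster["participant_id"], self.roster["followup_days"]))

    def arm_by_participant(self) -> dict:
        return dict(zip(self.roster["participant_id"], self.roster["arm"]))

    def severity_rank(self) -> dict[str, int]:
        return {grade: i for i, grade in enumerate(self.severity_scale)}

    def normal_range(self, outcome: str) -> tuple[float | None, float | None]:
        """(lower, upper) limits of normal for *outcome*; ``None`` when absent."""
        rows = self.ranges[self.ranges["outcome"] == outcome]
        if rows.empty:
            return (None, None)
        rec = rows.iloc[0]
        lower = None if pd.isna(rec["lower"]) else float(rec["lower"])
        upper = None if pd.isna(rec["upper"]) else float(rec["upper"])
        return (lower, upper)

    def subset_events(self, selector: str) -> pd.DataFrame:
        """Event rows matching *selector*: a term, a group, or ``"any"``.

        Resolution order: the literal ``"any"``, then term labels, then
        grouping labels.  Unknown selectors raise :class:`SelectorError`
        listing the available values.
        """
        if selector == ANY_EVENT:
            return self.events
        if (self.events["term"] == selector).any():
            return self.events[self.events["term"] == selector]
        if (self.events["group"] == selector).any():
            return self.events[self.events["group"] == selector]
        terms = sorted(self.events["term"].unique())
        groups = sorted(self.events["group"].unique())
        raise SelectorError(
            f"selector {selector!r} matches no event term or group; available "
            f"terms: {terms}; groups: {groups}; or use {ANY_EVENT!r}"
        )


def read_config(path: str | Path) -> dict:
    """Read a YAML config that may set ``severity_scale`` and ``ranges``.

    Returns a dict with optional keys ``severity_scale`` (ordered list) and
    ``ranges`` (DataFrame with the normal-range schema).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "severity_scale" in raw:
        out["severity_scale"] = tuple(raw["severity_scale"])
    if "ranges" in raw:
        out["ranges"] = pd.DataFrame(raw["ranges"], columns=list(RANGE_COLUMNS))
    return out


def read_trial(
    roster_path: str | Path,
    events_path: str | Path | None = None,
    measurements_path: str | Path | None = None,
    ranges_path: str | Path | None = None,
    severity_scale: Sequence[str] = DEFAULT_SEVERITY_SCALE,
    config_path: str | Path | None = None,
) -> TrialDataset:
    """Load and validate a trial from its CSV tables.

    ``config_path`` may point to a YAML file supplying ``severity_scale``
    and/or inline ``ranges``; explicit file arguments win over the config.
    """
    cfg = read_config(config_path) if config_path else {}
    if "severity_scale" in cfg:
        severity_scale = cfg["severity_scale"]

    roster = pd.read_csv(roster_path)
    events = pd.read_csv(events_path) if events_path else None
    measurements = pd.read_csv(measurements_path) if measurements_path else None
    if ranges_path:
        ranges = pd.read_csv(ranges_path)
    else:
        ranges = cfg.get("ranges")
    return TrialDataset.from_frames(
        roster, events, measurements, ranges, severity_scale=severity_scale
    )


def write_trial(dataset: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV tables to *out_dir*; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("roster", dataset.roster),
        ("events", dataset.events),
        ("measurements", dataset.measurements),
        ("ranges", dataset.ranges),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Derived per-participant views
# ---------------------------------------------------------------------------


def derive_first_event_times(dataset: TrialDataset, selector: str) -> pd.DataFrame:
    """Time to first matching event per roster participant.

    Returns one row per participant with columns ``participant_id``, ``arm``,
    ``time`` and ``status`` (1 = event at earliest matching onset, 0 =
    censored at end of follow-up).  This is the input for the Kaplan-Meier
    and survival-ratio estimators.
    """
    matching = dataset.subset_events(selector)
    first = matching.groupby("participant_id")["onset_day"].min()
    rows = []
    for _, rec in dataset.roster.iterrows():
        pid = rec["participant_id"]
        if pid in first.index:
            rows.append((pid, rec["arm"], float(first[pid]), 1))
        else:
            rows.append((pid, rec["arm"], float(rec["followup_days"]), 0))
    return pd.DataFrame(rows, columns=["participant_id", "arm", "time", "status"])


def derive_max_severity(dataset: TrialDataset, by: str = "group") -> pd.DataFrame:
    """Participants by arm, event label and their maximum observed grade.

    Each participant counts at most once per term/group, at the highest grade
    they recorded for it — a participant with a mild and a moderate occurrence
    of the same event counts once, as moderate.  Columns: ``arm``, *by*,
    ``severity``, ``n``.
    """
    if by not in ("term", "group"):
        raise ValueError("by must be 'term' or 'group'")
    ev = dataset.events
    if ev.empty:
        return pd.DataFrame(columns=["arm", by, "severity", "n"])
    rank = dataset.severity_rank()
    arm_of = dataset.arm_by_participant()
    worst = (
        ev.assign(_rank=ev["severity"].map(rank))
        .groupby(["participant_id", by])["_rank"]
        .max()
        .reset_index()
    )
    worst["arm"] = worst["participant_id"].map(arm_of)
    worst["severity"] = worst["_rank"].map(dict(enumerate(dataset.severity_scale)))
    out = (
        worst.groupby(["arm", by, "severity"], sort=False)
        .size()
        .reset_index(name="n")
    )
    out["_rank"] = out["severity"].map(rank)
    out = (
        out.sort_values(["arm", by, "_rank"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return out


def derive_event_counts(dataset: TrialDataset, selector: str) -> pd.DataFrame:
    """Distribution of events-per-participant by arm.

    Every roster participant lands in exactly one bin ``k`` (number of
    matching event records, k = 0 allowed); ``percent`` uses the arm roster
    size so percentages within an arm sum to 100.  Columns: ``arm``, ``k``,
    ``n``, ``percent``.
    """
    matching = dataset.subset_events(selector)
    per_pid = matching.groupby("participant_id").size()
    k = dataset.roster["participant_id"].map(per_pid).fillna(0).astype(int)
    tab = (
        pd.DataFrame({"arm": dataset.roster["arm"], "k": k})
        .groupby(["arm", "k"])
        .size()
        .reset_index(name="n")
    )
    sizes = dataset.arm_sizes()
    tab["percent"] = tab.apply(lambda r: 100.0 * r["n"] / sizes[r["arm"]], axis=1)
    return tab.sort_values(["arm", "k"]).reset_index(drop=True)


def derive_baseline_max(
    dataset: TrialDataset, outcome: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and maximum post-baseline value of *outcome* per participant.

    Returns ``(table, excluded)``: *table* has one row per participant with
    both a baseline (visit_time = 0) and at least one later value, with
    columns ``participant_id``, ``arm``, ``baseline``, ``maximum``;
    *excluded* reports participants missing either, with a ``reason``.
    """
    meas = dataset.measurements[dataset.measurements["outcome"] == outcome]
    if meas.empty:
        raise KeyError(
            f"outcome {outcome!r} not present; available: "
            f"{sorted(dataset.measurements['outcome'].unique())}"
        )
    arm_of = dataset.arm_by_participant()
    rows, excluded = [], []
    for pid in dataset.roster["participant_id"]:
        mine = meas[meas["participant_id"] == pid]
        if mine.empty:
            continue  # participant never measured for this outcome
        base = mine[mine["visit_time"] == 0]
        post = mine[mine["visit_time"] > 0]
        if base.empty:
            excluded.append((pid, arm_of[pid], "no baseline value"))
        elif post.empty:
            excluded.append((pid, arm_of[pid], "no post-baseline value"))
        else:
            rows.append(
                (pid, arm_of[pid], float(base["value"].iloc[0]), float(post["value"].max()))
            )
    table = pd.DataFrame(rows, columns=["participant_id", "arm", "baseline", "maximum"])
    excl = pd.DataFrame(excluded, columns=["participant_id", "arm", "reason"])
    return table, excl
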