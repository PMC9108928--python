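"""Independent brute-force oracles used to cross-check the estimators.

Deliberately written in the most literal style possible (explicit loops over
participants and times, no shared code with the package) so agreement with
the package implementations is a meaningful check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from harmviz.data_model import TrialDataset


def km_oracle(times, status):
    """Product-limit estimate by direct enumeration: S steps at event times."""
    times = list(map(float, times))
    status = list(map(int, status))
    event_times = sorted({t for t, s in zip(times, status) if s == 1})
    surv = []
    s_val = 1.0
    for u in event_times:
        at_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, s in zip(times, status) if t == u and s == 1)
        s_val *= 1.0 - d / at_risk
        surv.append(s_val)
    return np.array(event_times), np.array(surv)


def mcf_oracle(events_by_pid, followup_by_pid):
    """Mean cumulative function by direct enumeration of d(t)/Y(t)."""
    all_times = sorted({t for ts in events_by_pid.values() for t in ts})
    mcf = []
    running = 0.0
    for u in all_times:
        y = sum(1 for fu in followup_by_pid.values() if fu >= u)
        d = sum(1 for ts in events_by_pid.values() for t in ts if t == u)
        running += d / y
        mcf.append(running)
    return np.array(all_times), np.array(mcf)


def event_summary_oracle(dataset: TrialDataset, by: str):
    """(label, arm) -> (participants with >=1 event, event records) by sets."""
    arm_of = dataset.arm_by_participant()
    out = {}
    for label in dict.fromkeys(dataset.events[by]):
        for arm in dataset.arms:
            pids = set()
            n_records = 0
            for _, rec in dataset.events.iterrows():
                if rec[by] == label and arm_of[rec["participant_id"]] == arm:
                    pids.add(rec["participant_id"])
                    n_records += 1
            out[(label, arm)] = (len(pids), n_records)
    return out


def event_counts_oracle(dataset: TrialDataset, selector: str):
    """(arm, k) -> (n, percent) by per-participant tallying."""
    counts = {}
    for _, rec in dataset.roster.iterrows():
        pid, arm = rec["participant_id"], rec["arm"]
        if selector == "any":
            k = int((dataset.events["participant_id"] == pid).sum())
        else:
            match = dataset.events[
                (dataset.events["participant_id"] == pid)
                & (
                    (dataset.events["term"] == selector)
                    | (dataset.events["group"] == selector)
                )
            ]
            k = len(match)
        counts.setdefault((arm, k), 0)
        counts[(arm, k)] += 1
    sizes = dataset.arm_sizes()
    return {key: (n, 100.0 * n / sizes[key[0]]) for key, n in counts.items()}


def timepoint_oracle(dataset: TrialDataset, outcome: str):
    """(arm, visit) -> (n, mean, sd) by explicit accumulation."""
    arm_of = dataset.arm_by_participant()
    cells = {}
    for _, rec in dataset.measurements.iterrows():
        if rec["outcome"] != outcome:
            continue
        key = (arm_of[rec["participant_id"]], float(rec["visit_time"]))
        cells.setdefault(key, []).append(float(rec["value"]))
    out = {}
    for key, vals in cells.items():
        n = len(vals)
        mean = sum(vals) / n
        sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5 if n > 1 else 0.0
        out[key] = (n, mean, sd)
    return out


def random_tiny_dataset(rng: np.random.Generator, max_n: int = 12) -> TrialDataset:
    """A random small trial with integer times, ties, and recurrences."""
    n = int(rng.integers(2, max_n + 1))
    arms = ["A" if i < (n + 1) // 2 else "B" for i in range(n)]
    followup = rng.integers(5, 31, size=n).astype(float)
    roster = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "arm": arms,
            "followup_days": followup,
        }
    )
    terms = [("headache", "Nervous system"), ("nausea", "Gastrointestinal"),
             ("rash", "Skin")]
    grades = ["mild", "moderate", "severe"]
    rows = []
    for i in range(n):
        for _ in range(int(rng.poisson(1.0))):
            term, group = terms[rng.integers(0, len(terms))]
            rows.append(
                (
                    f"P{i}",
                    term,
                    group,
                    grades[rng.integers(0, 3)],
                    float(rng.integers(0, int(followup[i]) + 1)),
                )
            )
    events = pd.DataFrame(
        rows, columns=["participant_id", "term", "group", "severity", "onset_day"]
    )
    meas = []
    for i in range(n):
        for visit in (0.0, 5.0, 10.0):
            if rng.random() < 0.8:
                meas.append((f"P{i}", "lab", visit, float(rng.normal(50, 10))))
    measurements = pd.DataFrame(
        meas, columns=["participant_id", "outcome", "visit_time", "value"]
    )
    return TrialDataset.from_frames(roster, events, measurements)
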