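# harmviz

Visualising harm outcomes — adverse events, laboratory shifts, and
time-to-event safety signals — in randomised controlled trials.

Harms are chronically under-reported and under-analysed relative to benefits:
safety data arrive as long tables of low-frequency events across many body
systems, recurrent episodes, severity grades, and laboratory trajectories,
and no single summary statistic does them justice. `harmviz` implements a
consensus-endorsed set of **ten plots** for this setting, the estimators each
plot embeds, a decision tree for choosing among them, and a synthetic trial
generator so every estimator can be validated against known ground truth.

The package is aimed at trial statisticians and safety scientists who need
publication-ready harm displays from participant-level CSV data, and at
methodologists who want the estimators as a tested library.

## The plots and their statistics

| Outcome | Plot | Embedded statistic |
|---|---|---|
| multiple binary | dot plot | % with ≥1 event per arm; relative risk (or OR/RD/IRR) with 95% Wald CI |
| multiple binary + severity | stacked bar chart | participants by **maximum** severity grade |
| count (recurrent) | bar chart | % of participants by number of events k |
| single time-to-event | Kaplan-Meier plot | product-limit Ŝ(t), Greenwood variance, log(−log) bands, extended risk table |
| single time-to-event | survival ratio plot | Ŝ₁(t)/Ŝ₂(t) with pointwise percentile bootstrap bands |
| recurrent time-to-event | mean cumulative function plot | M̂(t) = Σ_{t_j ≤ t} d(t_j)/Y(t_j), Lawless–Nadeau variance |
| single continuous, repeated | line graph | per-visit mean ± SD (or median/IQR, or supplied model estimates) |
| single continuous, repeated, non-normal | violin plot | mirrored Gaussian KDE + median/IQR/min–max |
| single continuous, one time point | kernel density plot | Gaussian KDE, Silverman bandwidth 0.9·min(s, IQR/1.34)·n^(−1/5) |
| multiple continuous | scatterplot matrix | baseline vs maximum post-baseline value with normal-limit quadrants |

Comparative intervals are Wald throughout: for the relative risk the Katz
log-scale interval `exp(log RR ± z·SE)`, `SE = √(1/a − 1/n₁ + 1/b − 1/n₂)`;
when exactly one arm has zero events, half an event is added to each group's
numerator and denominator (flagged `corrected`). CIs here flag potential
signals for further investigation — they are deliberately *not* multiplicity-
adjusted hypothesis tests.

## Worked example

```python
import harmviz as hv
from harmviz import binary_stats as bs, data_model as dm, time_to_event as tte, figures

ds = hv.fixture_small()                       # 8 participants, 2 arms, documented values
summ = bs.summarize_by_event(ds, "group")
print(bs.summaries_to_frame(summ).to_string(index=False))
```

```
           label arm  arm_size  n_participants  n_events  percent
  Nervous system   A         4               2         3     50.0
  Nervous system   B         4               2         2     50.0
Gastrointestinal   A         4               1         1     25.0
Gastrointestinal   B         4               1         1     25.0
            Skin   A         4               0         0      0.0
            Skin   B         4               1         2     25.0
```

Two participants per arm had a nervous-system event (arm A accrued three
records because one participant's headache recurred); no-one in arm A had a
skin event. The comparative panel of the dot plot (arm B vs arm A):

```python
ordered, dropped = bs.dot_plot_estimates(summ, treatment_arm="B", control_arm="A")
print(bs.estimates_to_frame(ordered).to_string(index=False))
```

```
           label       measure  point   ci_low   ci_high  corrected
            Skin relative risk    3.0 0.161519 55.720833       True
Gastrointestinal relative risk    1.0 0.090677 11.028202      False
  Nervous system relative risk    1.0 0.250098  3.998438      False
```

The skin row used the half-event correction (0 events in arm A): point
(1.5/4.5)/(0.5/4.5) = 3.0 with a very wide interval, honestly reflecting
four participants per arm. Kaplan-Meier for time to first event in arm A:

```python
first = dm.derive_first_event_times(ds, "any")
km = tte.km_estimate(first[first["arm"] == "A"], arm="A")
print(km.to_frame().to_string(index=False))
```

```
arm  time  estimate  variance   ci_low  ci_high kind
  A   5.0      0.75  0.046875 0.127947 0.960549   km
  A  10.0      0.50  0.062500 0.057847 0.844861   km
  A  20.0      0.25  0.046875 0.008948 0.665325   km
```

Events at days 5, 10 and 20 step the survival from 1 to 3/4, 1/2 and 1/4;
the fourth participant is censored at day 100. Any builder in
`harmviz.figures` returns the figure **plus** this exact table
(`artifact.table`), and `artifact.save(dir)` writes SVG/PDF/PNG and CSV.

From the shell:

```sh
harmviz simulate --seed 3 --out-dir trial/          # synthetic two-arm trial CSVs
harmviz plot dot-plot --roster trial/roster.csv --events trial/events.csv --out-dir figs/
harmviz recommend --outcome-type time-to-event --multiplicity multiple
# -> No suitable endorsed plot for these characteristics.
```

## Scope notes

Competing risks are not modelled: when a terminal competing event precludes
the harm of interest, use cumulative-incidence methods (Aalen–Johansen,
Fine–Gray) instead of the estimators here. Mixed-model per-visit estimates
are accepted as pre-computed input for the line graph, not fitted.
Interactive displays, MedDRA coding, and multiplicity-adjusted testing are
out of scope. See `docs/methods.md` for estimator details and design
rationale.
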