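# Methods

This note documents the statistical procedures, their assumptions, the
numerical choices that were genuinely open, and what the synthetic-data
checks do and do not establish.

## Data model and conventions

Time is measured in days since randomisation, with t = 0 at randomisation
and observation ending at `followup_days` on a half-open [0, followup]
scale. An event recorded on the same day as censoring counts as an event
(ties process events before censorings throughout). The denominator for all
percentages is the roster as supplied — i.e. the safety population is
whatever population the caller loads; subsetting to a treated population is
the caller's responsibility, since trial conventions differ on whether
denominators are randomised or treated participants.

The severity scale is configurable (default mild < moderate < severe; a
five-grade scale is accepted the same way). An event row with no
body-system grouping is assigned to "Other" rather than rejected. Validation
is total: any row violating a typed invariant produces a row-addressed
error, and valid files round-trip losslessly through CSV.

## Binary and count comparisons

Effect measures are relative risk, odds ratio, risk difference, and
incidence rate ratio. All intervals are Wald with half-width
z(1 − α/2)·SE, α = 0.05 by default:

* RR (Katz): SE = √(1/a − 1/n₁ + 1/b − 1/n₂) on the log scale;
* OR: SE = √(1/a + 1/(n₁−a) + 1/b + 1/(n₂−b)) on the log scale;
* RD: SE = √(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂) on the identity scale;
* IRR: SE = √(1/e₁ + 1/e₂) on the log scale.

Wald was chosen because it is the interval the field's standard safety-plot
tooling computes and the simplest construction consistent with "point ± z
standard errors"; exact and score intervals are deliberately out of scope.
When exactly one arm records zero events, 0.5 is added to each group's
numerator and denominator (counts only, for the IRR) before estimation and
the result is flagged `corrected`. The correction is defined only for the
single-zero case; double-zero rows raise a no-estimate error and are listed
separately by the dot-plot ordering so the figure can footnote them. This
correction is known to behave poorly in rare-event meta-analysis; within a
single trial's descriptive display it is an acceptable, transparent default.

No multiplicity adjustment is applied anywhere: the intervals are signal-
flagging devices, not hypothesis tests, and adjusting them would change
their meaning.

## Time-to-event estimators

**Kaplan-Meier.** Product-limit over distinct event times, Greenwood
variance, and confidence bands via the complementary log-log transform
(bands stay inside [0, 1] without clipping; at Ŝ ∈ {0, 1} the band is
degenerate at the estimate). The estimator assumes non-informative
censoring and no competing risks; with competing terminal events it
overstates cumulative risk and a cumulative-incidence estimator
(Aalen–Johansen / Fine–Gray) should be used instead — this caution is
repeated in the user documentation because harm analyses are particularly
exposed to it.

**Extended risk table.** At each grid time t: cumulative events and
censorings count occurrences in (0, t] (the t = 0 row is the boundary —
full arm at risk, zeros elsewhere — so day-0 events appear from the first
positive grid point), and at-risk = arm size − (cum events + cum censored).
This makes the three columns conserve the arm size at every grid point, the
invariant the tests assert.

**Mean cumulative function.** M̂(t) = Σ_{t_j ≤ t} d(t_j)/Y(t_j) with
d(t_j) the events at t_j (recurrences included) and Y(t_j) the participants
still under observation. The variance is the Lawless–Nadeau robust
estimator: per-participant cumulative residuals
e_i(t) = Σ_{t_j ≤ t, i at risk} (d_ij − d_j/Y_j)/Y_j, with
Var̂ = Σ_i e_i(t)², which respects within-participant correlation of
recurrences. Bands are log-scale, so the lower bound is non-negative.

**Survival ratio.** Ŝ_ref(t)/Ŝ_cmp(t) evaluated on the union of the two
arms' event-time grids, truncated where either estimate reaches zero (the
ratio is undefined there). Bands are pointwise percentile intervals over
participant-level bootstrap resamples within each arm; the interval type was
an open choice and percentile was selected for its simplicity and
transform-invariance, accepting its known slight undercoverage at moderate
n (the acceptance check measures the realised coverage directly). A
degenerate resample in which every drawn participant is censored evaluates
to a flat Ŝ = 1 rather than erroring. A resampled comparator arm that runs
out of survivors contributes +inf to the band; two adjacent infinite order
statistics interpolate to +inf, not NaN. The seed is a required argument:
bands are bit-reproducible by construction. The reference arm is always the
numerator and is recorded in the output metadata. A difference mode
(Ŝ₁ − Ŝ₂, null at 0) reuses the same machinery; its interval is likewise
percentile bootstrap.

## Continuous summaries

Per-visit summaries are computed at observed visit times only — no
interpolation between visits. Means are paired with the standard deviation
(describing individual variability), not the standard error; medians with
the interquartile range using linear interpolation of order statistics
(numpy default, "type 7"), fixed and documented for reproducibility. A
single observation yields zero spread. Model-based per-visit estimates
(e.g. MMRM means with 95% CIs) enter as pre-computed rows of
`statistic_kind="model_ci"`; fitting repeated-measures models is out of
scope.

The kernel density estimator uses a Gaussian kernel, Silverman's rule
0.9·min(s, IQR/1.34)·n^(−1/5) (falling back to s when the IQR is zero), a
512-point grid spanning the data ± 3 bandwidths, and no boundary
correction — for non-negative outcomes like eosinophil counts the estimate
can extend below zero, a known cosmetic artefact that is displayed rather
than hidden. Samples without two distinct values raise an error advising a
raw-point display.

Change scores subtract baseline (visit 0) from either the value at a named
visit or the maximum over *all* post-baseline visits; when treatment stops
before the last visit the maximum still includes post-treatment visits —
callers needing an on-treatment window should subset the measurements
first. Participants lacking a required value are excluded and reported, not
silently dropped.

## Figures

Every builder returns the figure together with the unmodified statistics
table it displays, and records its resolved options (including the per-arm
style map and, where relevant, drawn segment geometry) so tests can assert
on what was actually rendered. Defaults: colour-blind-safe Okabe-Ito
palette; `grayscale=True` switches to black with distinct line styles,
markers and hatches per arm. The dot plot's absolute axis spans
[0, 1.1 × max %] rather than 0–100 so rare events stay readable; its data
table sits in the right panel by default (centre optional). Stacked-severity
bars order events by descending total frequency by default (configurable)
and place the most severe grade against the axis. The bar chart draws ≤ 2
arms side by side and one stacked panel per arm beyond that. Figure output
is vector-first (SVG/PDF) with PNG fallback.

## Decision tree

The characteristics-to-plot mapping is implemented as a total function over
a validated spec lattice. Two cells were genuinely open: (1) a single
continuous repeated outcome returns the line graph with the violin noted as
the alternative when the distribution is roughly normal, and the violin
with the line graph noted otherwise; (2) count-type outcomes map to the bar
chart regardless of multiplicity. A single non-recurrent binary outcome has
no endorsed plot of its own; the recommendation is an explicit empty result
advising a numeric summary or a time-to-event recast when onset times
exist. Branches of the source decision process that distinguish emerging
from prespecified events are not expressible in the spec and are documented
here as a limitation rather than guessed. Every recommendation carries the
caveat that the trial team must make the final choice.

## Synthetic data

The generator emulates a two-arm parallel RCT: exponential non-informative
dropout (per-year hazard, truncated at nominal follow-up), homogeneous
Poisson recurrent events per body-system group with arm-specific rates,
one-off events with arm-specific probabilities at uniform times, iid
severity draws from a configured mixture, and lab values as participant
baseline draw + arm×visit effect + residual noise, recorded only at visits
within follow-up. One master seed spawns independent substreams per
component, so adding a lab outcome leaves the event stream untouched.

The bundled default (300/arm, one year, six body systems with incidence
ratios of 1.2–2.3, a recurrent headache group at 0.8 vs 1.6 events per
participant-year, an eosinophil-like outcome with ULN 0.5 × 10⁹/L) was
chosen once to resemble published safety tables and is not tuned.

What it does *not* emulate: informative censoring, competing risks,
time-varying rates, cross-system correlation of susceptibility, or coded
dictionary structure. Passing tests therefore demonstrate estimator
correctness under the estimators' own assumptions — they do not certify
behaviour under informative dropout or competing mortality.

## Problem sizes in the checks

Oracle-agreement checks use 200 random trials of ≤ 12 participants
(exhaustively enumerable by the brute-force implementations). Coverage
checks use 500 replicates at 200/arm for the Wald null, and 200 outer
replicates × 500 bootstrap draws at 200/arm for the survival-ratio band
(tolerance 95 ± 3 percentage points, the Monte-Carlo resolution of 200
replicates). Rate-ratio recovery uses 2000/arm over one year, giving ~6000
events and a relative Monte-Carlo error under 3%.
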