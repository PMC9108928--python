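import numpy as np
import pandas as pd
import pytest

from harmviz import binary_stats as bs
from harmviz import continuous_stats as cs
from harmviz import data_model as dm
from harmviz import figures as fg
from harmviz import time_to_event as tte


def _first_per_arm(ds, selector="any"):
    first = dm.derive_first_event_times(ds, selector)
    return {a: first[first["arm"] == a] for a in ds.arms}


def _km_inputs(ds):
    per_arm = _first_per_arm(ds)
    curves = [tte.km_estimate(r, arm=a) for a, r in per_arm.items()]
    rt = tte.extended_risk_table(per_arm, [0, 25, 50, 75, 100])
    return curves, rt


def _mcf_inputs(ds):
    fu = ds.followup_by_participant()
    arm_of = ds.arm_by_participant()
    curves = []
    for arm in ds.arms:
        pids = [p for p in fu if arm_of[p] == arm]
        ev = {p: ds.events[ds.events["participant_id"] == p]["onset_day"].tolist()
              for p in pids}
        curves.append(tte.mcf_estimate(ev, {p: fu[p] for p in pids}, arm=arm))
    rt = tte.extended_risk_table(_first_per_arm(ds), [0, 25, 50, 75, 100])
    return curves, rt


class TestDotPlot:
    def _build(self, ds, measure=bs.RELATIVE_RISK, **opts):
        summaries = bs.summarize_by_event(ds, "group")
        ordered, dropped = bs.dot_plot_estimates(summaries, "B", "A", measure=measure)
        return summaries, ordered, dropped, fg.plot_dot(
            summaries, ordered, opts or None, dropped=dropped
        )

    def test_three_panels_with_log_axis_and_null_line(self, ds):
        _, ordered, _, art = self._build(ds)
        assert len(art.figure.axes) == 3
        assert art.options["null_value"] == 1.0
        assert art.figure.axes[1].get_xscale() == "log"

    def test_risk_difference_uses_linear_axis_null_zero(self, ds):
        _, _, _, art = self._build(ds, measure=bs.RISK_DIFFERENCE)
        assert art.options["null_value"] == 0.0
        assert art.figure.axes[1].get_xscale() == "linear"

    def test_table_equals_statistics_output(self, ds):
        summaries, ordered, _, art = self._build(ds)
        pd.testing.assert_frame_equal(
            art.table["events"], bs.summaries_to_frame(summaries)
        )
        pd.testing.assert_frame_equal(
            art.table["effects"], bs.estimates_to_frame(ordered)
        )

    def test_rows_ordered_highest_estimate_first(self, ds):
        _, ordered, dropped, art = self._build(ds)
        assert art.options["row_order"][: len(ordered)] == [l for l, _ in ordered]

    def test_mismatched_event_lists_rejected(self, ds):
        summaries = bs.summarize_by_event(ds, "group")
        ordered, _ = bs.dot_plot_estimates(summaries, "B", "A")
        with pytest.raises(fg.FigureError):
            fg.plot_dot(summaries[:-1], ordered)

    def test_absolute_axis_guard(self, ds):
        summaries, _, _, art = self._build(ds)
        max_pct = max(c.percent for s in summaries for c in s.per_arm.values())
        assert art.figure.axes[0].get_xlim()[1] == pytest.approx(max_pct * 1.1)


class TestStackedSeverity:
    def test_most_severe_innermost_on_fixture(self, ds):
        tab = dm.derive_max_severity(ds, "term")
        art = fg.plot_stacked_severity(tab, ds.arm_sizes(), ds.severity_scale)
        seg = art.options["segments"]
        head_a = seg[(seg["event"] == "headache") & (seg["arm"] == "A")]
        by_grade = head_a.set_index("severity")
        # severe starts at the axis; moderate stacks outward
        assert by_grade.loc["severe", "left"] == 0.0
        assert by_grade.loc["moderate", "left"] == by_grade.loc["severe", "width"]

    def test_total_bar_equals_percent_with_event(self, ds):
        tab = dm.derive_max_severity(ds, "term")
        art = fg.plot_stacked_severity(tab, ds.arm_sizes(), ds.severity_scale)
        seg = art.options["segments"]
        sizes = ds.arm_sizes()
        arm_of = ds.arm_by_participant()
        for (event, arm), sub in seg.groupby(["event", "arm"]):
            pids = {p for p in ds.events[ds.events["term"] == event]["participant_id"]
                    if arm_of[p] == arm}
            assert sub["width"].sum() == pytest.approx(100 * len(pids) / sizes[arm])

    def test_zero_event_arm_zero_length_bar(self, ds):
        tab = dm.derive_max_severity(ds, "term")
        art = fg.plot_stacked_severity(tab, ds.arm_sizes(), ds.severity_scale)
        seg = art.options["segments"]
        rash_a = seg[(seg["event"] == "rash") & (seg["arm"] == "A")]
        assert rash_a["width"].sum() == 0.0
        assert rash_a["n"].sum() == 0

    def test_table_is_input_unchanged(self, ds):
        tab = dm.derive_max_severity(ds, "term")
        art = fg.plot_stacked_severity(tab, ds.arm_sizes(), ds.severity_scale)
        pd.testing.assert_frame_equal(art.table, dm.derive_max_severity(ds, "term"))


class TestCountBars:
    def test_two_arms_single_panel(self, ds):
        art = fg.plot_count_bars(dm.derive_event_counts(ds, "any"))
        assert art.options["n_panels"] == 1

    def test_three_arms_stacked_panels_shared_axes(self):
        tab = pd.DataFrame(
            {
                "arm": ["A", "A", "B", "B", "C", "C"],
                "k": [0, 1, 0, 1, 0, 1],
                "n": [5, 5, 6, 4, 7, 3],
                "percent": [50.0, 50.0, 60.0, 40.0, 70.0, 30.0],
            }
        )
        art = fg.plot_count_bars(tab)
        assert art.options["n_panels"] == 3
        limits = {ax.get_ylim() for ax in art.figure.axes}
        assert len(limits) == 1

    def test_bar_heights_equal_percentages(self, ds):
        tab = dm.derive_event_counts(ds, "any")
        art = fg.plot_count_bars(tab)
        heights = sorted(
            round(p.get_height(), 9) for p in art.figure.axes[0].patches
        )
        assert heights == sorted(round(v, 9) for v in tab["percent"])

    def test_table_fidelity(self, ds):
        tab = dm.derive_event_counts(ds, "any")
        art = fg.plot_count_bars(tab)
        pd.testing.assert_frame_equal(art.table, dm.derive_event_counts(ds, "any"))


class TestKMPlot:
    def test_all_censored_single_arm_flat_at_one(self):
        recs = pd.DataFrame({"time": [50.0, 80.0], "status": [0, 0]})
        curve = tte.km_estimate(recs, arm="A")
        rt = tte.extended_risk_table({"A": recs}, [0, 40, 80])
        art = fg.plot_km([curve], rt)
        y = art.figure.axes[0].lines[0].get_ydata()
        assert np.all(y == 1.0)

    def test_reversed_axis_non_decreasing_from_zero(self, ds):
        curves, rt = _km_inputs(ds)
        art = fg.plot_km(curves, rt, {"reversed_axis": True})
        for line in art.figure.axes[0].lines:
            y = line.get_ydata()
            assert y[0] == 0.0
            assert np.all(np.diff(y) >= 0)

    def test_risk_table_fidelity(self, ds):
        curves, rt = _km_inputs(ds)
        art = fg.plot_km(curves, rt)
        pd.testing.assert_frame_equal(art.table["risk_table"], rt.table)
        pd.testing.assert_frame_equal(
            art.table["curves"],
            pd.concat([c.to_frame() for c in curves], ignore_index=True),
        )

    def test_arm_mismatch_rejected(self, ds):
        curves, rt = _km_inputs(ds)
        with pytest.raises(fg.FigureError):
            fg.plot_km(curves[:1], rt)

    def test_wrong_curve_kind_rejected(self, ds):
        mcurves, rt = _mcf_inputs(ds)
        with pytest.raises(fg.FigureError):
            fg.plot_km(mcurves, rt)


class TestMCFPlot:
    def test_no_event_arm_flat_zero(self):
        curve = tte.mcf_estimate({}, {"P1": 50.0, "P2": 50.0}, arm="A")
        recs = pd.DataFrame({"time": [50.0, 50.0], "status": [0, 0]})
        rt = tte.extended_risk_table({"A": recs}, [0, 25, 50])
        art = fg.plot_mcf([curve], rt)
        y = art.figure.axes[0].lines[0].get_ydata()
        assert np.all(y == 0.0)

    def test_bands_suppressed_when_requested(self, ds):
        curves, rt = _mcf_inputs(ds)
        with_bands = fg.plot_mcf(curves, rt)
        without = fg.plot_mcf(curves, rt, {"show_bands": False})
        n_coll_with = len(with_bands.figure.axes[0].collections)
        n_coll_without = len(without.figure.axes[0].collections)
        assert n_coll_without < n_coll_with

    def test_step_heights_equal_estimates(self, ds):
        curves, rt = _mcf_inputs(ds)
        art = fg.plot_mcf(curves, rt)
        for line, curve in zip(art.figure.axes[0].lines, curves):
            y = line.get_ydata()
            assert np.allclose(sorted(set(y)), sorted(set([0.0, *curve.estimate])))


class TestSurvivalRatioPlot:
    def test_identical_arms_flat_unity_all_green(self, ds):
        recs = dm.derive_first_event_times(ds, "any")
        arm = recs[recs["arm"] == "A"]
        rc = tte.survival_ratio(arm, arm, n_boot=50, seed=1)
        art = fg.plot_survival_ratio(rc)
        assert np.allclose(rc.ratio, 1.0)
        assert all(not excl for _, _, excl in art.options["indicator_segments"])

    def test_indicator_segments_match_flags(self, ds):
        per_arm = _first_per_arm(ds)
        rc = tte.survival_ratio(per_arm["A"], per_arm["B"], n_boot=100, seed=3)
        art = fg.plot_survival_ratio(rc)
        flat = []
        for t0, t1, excl in art.options["indicator_segments"]:
            for i, t in enumerate(rc.times):
                if t0 <= t < t1 or (t == t1 == rc.times[-1] and t1 == t0):
                    flat.append((i, excl))
        for i, excl in flat:
            assert bool(rc.excludes_unity[i]) == excl

    def test_difference_mode_reference_at_zero(self, ds):
        per_arm = _first_per_arm(ds)
        rc = tte.survival_ratio(per_arm["A"], per_arm["B"], n_boot=20, seed=2,
                                mode="difference")
        art = fg.plot_survival_ratio(rc)
        assert art.options["null_value"] == 0.0


class TestLineGraph:
    def test_marker_values_equal_summaries(self, ds):
        summary = cs.summarize_timepoints(ds, "eosinophils")
        art = fg.plot_line(summary, ds.normal_range("eosinophils"))
        pd.testing.assert_frame_equal(art.table, summary)
        # errorbar adds two cap lines after each arm's data line
        data_lines = art.figure.axes[0].lines[0::3]
        for line, arm in zip(data_lines, ["A", "B"]):
            sub = summary[summary["arm"] == arm].sort_values("visit_time")
            assert np.allclose(
                line.get_ydata().astype(float), sub["center"].to_numpy()
            )

    def test_reference_lines_at_configured_limits(self, ds):
        summary = cs.summarize_timepoints(ds, "eosinophils")
        art = fg.plot_line(summary, (0.02, 0.5))
        hlines = [l.get_ydata()[0] for l in art.figure.axes[0].lines
                  if len(set(l.get_ydata())) == 1]
        assert 0.02 in hlines and 0.5 in hlines

    def test_missing_range_warns_and_renders(self, ds):
        summary = cs.summarize_timepoints(ds, "eosinophils")
        with pytest.warns(UserWarning, match="normal range"):
            art = fg.plot_line(summary, (None, None))
        assert art.figure is not None


class TestViolin:
    def test_table_equals_median_iqr_summary(self, ds):
        art = fg.plot_violin(ds, "eosinophils")
        pd.testing.assert_frame_equal(
            art.table, cs.summarize_timepoints(ds, "eosinophils", cs.MEDIAN_IQR)
        )

    def test_half_violin_option_recorded(self, ds):
        art = fg.plot_violin(ds, "eosinophils", {"half_violin": True})
        assert art.options["half_violin"] is True

    def test_degenerate_cell_rendered_without_density(self, ds):
        meas = pd.DataFrame(
            {
                "participant_id": ["P1", "P2", "P3"],
                "outcome": "flat",
                "visit_time": 0.0,
                "value": [1.0, 1.0, 1.0],
            }
        )
        d = dm.TrialDataset.from_frames(
            ds.roster, measurements=pd.concat([ds.measurements, meas],
                                              ignore_index=True),
            ranges=ds.ranges,
        )
        art = fg.plot_violin(d, "flat")  # must not raise
        assert art.kind == "violin plot"


class TestKDEPlot:
    def test_identical_arm_samples_identical_curves(self):
        vals = np.array([1.0, 2.0, 3.0, 5.0])
        art = fg.plot_kde({"A": vals, "B": vals.copy()})
        l1, l2 = art.figure.axes[0].lines[:2]
        assert np.array_equal(l1.get_ydata(), l2.get_ydata())

    def test_reference_line_at_uln_390(self):
        """With an alkaline-phosphatase-style ULN of 390 U/L configured, the
        plot draws a vertical reference line at exactly 390."""
        rng = np.random.default_rng(0)
        art = fg.plot_kde(
            {"A": rng.normal(100, 30, 50), "B": rng.normal(150, 80, 50)},
            normal_range=(None, 390.0),
        )
        vlines = [l.get_xdata()[0] for l in art.figure.axes[0].lines
                  if len(set(l.get_xdata())) == 1]
        assert 390.0 in vlines

    def test_curves_equal_kde_module_output(self, ds):
        scores, _ = cs.change_scores(ds, "eosinophils")
        values = {a: scores[scores["arm"] == a]["score"].to_numpy() for a in ds.arms}
        art = fg.plot_kde(values)
        for arm in ds.arms:
            dens = cs.kde(values[arm])
            sub = art.table[art.table["arm"] == arm]
            assert np.allclose(sub["density"].to_numpy(), dens.density)
            assert np.allclose(sub["x"].to_numpy(), dens.grid)


class TestScatterMatrix:
    def _inputs(self, ds):
        outcomes = ["eosinophils", "alkaline phosphatase"]
        tables = {oc: dm.derive_baseline_max(ds, oc)[0] for oc in outcomes}
        ranges = {oc: ds.normal_range(oc) for oc in outcomes}
        return tables, ranges

    def test_panel_count_equals_outcomes(self, ds):
        tables, ranges = self._inputs(ds)
        art = fg.plot_scatter_matrix(tables, ranges)
        assert art.options["n_panels"] == 2

    def test_abnormal_maximum_labelled(self, ds):
        tables, ranges = self._inputs(ds)
        art = fg.plot_scatter_matrix(tables, ranges)
        # P5's alkaline phosphatase maximum (420) exceeds the ULN (390)
        assert "P5" in art.options["labelled"]["alkaline phosphatase"]

    def test_all_normal_no_labels(self):
        tab = pd.DataFrame(
            {
                "participant_id": ["P1", "P2"],
                "arm": ["A", "B"],
                "baseline": [50.0, 60.0],
                "maximum": [55.0, 65.0],
            }
        )
        art = fg.plot_scatter_matrix({"lab": tab}, {"lab": (10.0, 100.0)})
        assert art.options["labelled"]["lab"] == []

    def test_table_fidelity(self, ds):
        tables, ranges = self._inputs(ds)
        art = fg.plot_scatter_matrix(tables, ranges)
        for oc, tab in tables.items():
            pd.testing.assert_frame_equal(art.table[oc], tab)


class TestGrayscale:
    @pytest.mark.parametrize("builder", ["dot", "km", "line", "kde"])
    def test_grayscale_styles_distinct_per_arm(self, ds, builder):
        opts = {"grayscale": True}
        if builder == "dot":
            summaries = bs.summarize_by_event(ds, "group")
            ordered, dropped = bs.dot_plot_estimates(summaries, "B", "A")
            art = fg.plot_dot(summaries, ordered, opts, dropped=dropped)
        elif builder == "km":
            curves, rt = _km_inputs(ds)
            art = fg.plot_km(curves, rt, opts)
        elif builder == "line":
            art = fg.plot_line(cs.summarize_timepoints(ds, "eosinophils"),
                               ds.normal_range("eosinophils"), opts)
        else:
            scores, _ = cs.change_scores(ds, "eosinophils")
            art = fg.plot_kde(
                {a: scores[scores["arm"] == a]["score"].to_numpy() for a in ds.arms},
                options=opts,
            )
        styles = art.options["arm_styles"]
        combos = {
            (s["linestyle"], s["marker"], s["hatch"]) for s in styles.values()
        }
        assert len(combos) == len(styles)
        assert all(s["color"] == "black" for s in styles.values())
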