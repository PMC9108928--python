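import numpy as np
import pandas as pd
import pytest

from harmviz import data_model as dm
from harmviz import time_to_event as tte
from oracles import km_oracle, mcf_oracle, random_tiny_dataset


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = tte.km_estimate([(1, 1), (2, 1), (3, 0), (4, 1)])
        assert list(curve.times) == [1.0, 2.0, 4.0]
        assert np.allclose(curve.estimate, [3 / 4, 1 / 2, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = tte.km_estimate([(5, 0), (10, 0), (12, 0)])
        assert curve.times.size == 0
        assert np.all(curve.evaluate([0, 6, 20]) == 1.0)

    def test_no_censoring_is_one_minus_ecdf(self):
        rng = np.random.default_rng(7)
        times = rng.integers(1, 20, size=30).astype(float)
        curve = tte.km_estimate([(t, 1) for t in times])
        for u in np.unique(times):
            assert curve.evaluate([u])[0] == pytest.approx(np.mean(times > u))

    def test_ties_events_before_censorings(self):
        # censored at 5 still at risk for the event at 5
        curve = tte.km_estimate([(5, 1), (5, 0), (10, 0)])
        assert curve.estimate[0] == pytest.approx(2 / 3)

    def test_monotone_non_increasing_within_unit(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(2, 30)
            recs = list(zip(rng.integers(0, 15, n).astype(float), rng.integers(0, 2, n)))
            if not any(s for _, s in recs):
                continue
            c = tte.km_estimate(recs)
            assert np.all(np.diff(c.estimate) <= 1e-15)
            assert c.estimate[0] <= 1.0
            assert np.all((c.ci_low <= c.estimate + 1e-12) & (c.estimate <= c.ci_high + 1e-12))
            assert np.all((c.ci_low >= 0) & (c.ci_high <= 1))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(1, 13)
            times = rng.integers(0, 12, size=n).astype(float)
            status = rng.integers(0, 2, size=n)
            if status.sum() == 0:
                continue
            curve = tte.km_estimate(list(zip(times, status)))
            ot, os_ = km_oracle(times, status)
            assert np.array_equal(curve.times, ot)
            assert np.allclose(curve.estimate, os_, atol=1e-12)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times = rng.exponential(50, 80)
        status = rng.integers(0, 2, 80)
        curve = tte.km_estimate(list(zip(times, status)))
        kmf = lifelines.KaplanMeierFitter().fit(times, status)
        ours = curve.evaluate(curve.times)
        theirs = kmf.predict(curve.times).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tte.km_estimate([])


class TestRiskTable:
    def _records(self):
        return {"A": [(1, 1), (2, 1), (3, 0), (4, 1)]}

    def test_boundary_row_at_zero(self):
        rt = tte.extended_risk_table(self._records(), [0, 2, 4])
        row0 = rt.for_arm("A").iloc[0]
        assert (row0["at_risk"], row0["cum_censored"], row0["cum_events"]) == (4, 0, 0)

    def test_hand_counts_on_fixture(self):
        rt = tte.extended_risk_table(self._records(), [0, 2, 4]).for_arm("A")
        assert list(rt["at_risk"]) == [4, 2, 0]
        assert list(rt["cum_events"]) == [0, 2, 3]
        assert list(rt["cum_censored"]) == [0, 0, 1]

    def test_grid_beyond_followup_conserves_arm_size(self):
        rt = tte.extended_risk_table(self._records(), [0, 50]).for_arm("A")
        last = rt.iloc[-1]
        assert last["at_risk"] == 0
        assert last["cum_censored"] + last["cum_events"] == 4

    def test_conservation_at_every_grid_point(self, ds):
        first = dm.derive_first_event_times(ds, "any")
        per_arm = {a: first[first["arm"] == a] for a in ds.arms}
        rt = tte.extended_risk_table(per_arm, [0, 20, 40, 60, 80, 100])
        sizes = ds.arm_sizes()
        for arm in ds.arms:
            sub = rt.for_arm(arm)
            total = sub["at_risk"] + sub["cum_censored"] + sub["cum_events"]
            assert (total == sizes[arm]).all()

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            tte.extended_risk_table(self._records(), [1, 2])
        with pytest.raises(ValueError):
            tte.extended_risk_table(self._records(), [0, 2, 2])


class TestMCF:
    def test_hand_increments(self):
        curve = tte.mcf_estimate({"A": [1, 2], "B": []}, {"A": 3, "B": 3})
        assert list(curve.times) == [1.0, 2.0]
        assert np.allclose(curve.estimate, [0.5, 1.0])

    def test_no_events_identically_zero(self):
        curve = tte.mcf_estimate({}, {"A": 10, "B": 5})
        assert curve.times.size == 0
        assert curve.evaluate([0, 3, 10])[0] == 0.0

    def test_no_censoring_ends_at_mean_count(self):
        events = {"A": [1, 4, 6], "B": [2], "C": []}
        curve = tte.mcf_estimate(events, {"A": 10, "B": 10, "C": 10})
        assert curve.estimate[-1] == pytest.approx(4 / 3)

    def test_monotone_non_decreasing_with_valid_bands(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 12)
            fu = {f"P{i}": float(rng.integers(3, 20)) for i in range(n)}
            ev = {
                p: sorted(rng.integers(0, int(f) + 1, rng.poisson(2)).astype(float))
                for p, f in fu.items()
            }
            c = tte.mcf_estimate(ev, fu)
            if c.times.size == 0:
                continue
            assert np.all(np.diff(c.estimate) > 0)
            assert np.all(c.ci_low >= 0)
            assert np.all((c.ci_low <= c.estimate + 1e-12) & (c.estimate <= c.ci_high + 1e-12))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = rng.integers(1, 13)
            fu = {f"P{i}": float(rng.integers(2, 15)) for i in range(n)}
            ev = {
                p: list(rng.integers(0, int(f) + 1, rng.poisson(1.5)).astype(float))
                for p, f in fu.items()
            }
            curve = tte.mcf_estimate(ev, fu)
            ot, om = mcf_oracle(ev, fu)
            assert np.array_equal(curve.times, ot)
            assert np.allclose(curve.estimate, om, atol=1e-12)

    def test_event_beyond_followup_rejected(self):
        with pytest.raises(ValueError):
            tte.mcf_estimate({"A": [5]}, {"A": 3})

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            tte.mcf_estimate({}, {})


class TestSurvivalRatio:
    def _arm(self, seed, n=40):
        rng = np.random.default_rng(seed)
        t = rng.exponential(30, n)
        c = rng.uniform(10, 60, n)
        return [(min(ti, ci), int(ti <= ci)) for ti, ci in zip(t, c)]

    def test_identical_arms_unity(self):
        arm = self._arm(1)
        rc = tte.survival_ratio(arm, arm, n_boot=100, seed=9)
        assert np.allclose(rc.ratio, 1.0)
        assert not rc.excludes_unity.any()

    def test_point_ratio_arithmetic(self):
        rc = tte.survival_ratio(
            [(10, 1), (20, 0)], [(5, 1), (5, 1), (20, 0), (20, 0)],
            n_boot=10, seed=0,
        )
        # at t=10: S1 = 0.5, S2 = 0.5 -> 1.0; at t=5: S1 = 1, S2 = 0.5 -> 2.0
        idx5 = list(rc.times).index(5.0)
        idx10 = list(rc.times).index(10.0)
        assert rc.ratio[idx5] == pytest.approx(2.0)
        assert rc.ratio[idx10] == pytest.approx(1.0)

    def test_swapped_arms_reciprocal_pointwise(self):
        a1, a2 = self._arm(2), self._arm(3)
        fwd = tte.survival_ratio(a1, a2, n_boot=10, seed=4)
        rev = tte.survival_ratio(a2, a1, n_boot=10, seed=4)
        assert np.array_equal(fwd.times, rev.times)
        assert np.allclose(fwd.ratio, 1.0 / rev.ratio, atol=1e-12)

    def test_fixed_seed_bit_reproducible(self):
        a1, a2 = self._arm(5), self._arm(6)
        one = tte.survival_ratio(a1, a2, n_boot=50, seed=42)
        two = tte.survival_ratio(a1, a2, n_boot=50, seed=42)
        assert np.array_equal(one.ci_low, two.ci_low)
        assert np.array_equal(one.ci_high, two.ci_high)

    def test_grid_truncated_where_survival_zero(self):
        rc = tte.survival_ratio(
            [(1, 1), (2, 1)], [(1, 1), (3, 1)], n_boot=10, seed=1
        )
        # S1 hits 0 at t=2: grid stops before
        assert rc.times.max() < 2.0

    def test_difference_mode_null_zero(self):
        a1, a2 = self._arm(8), self._arm(9)
        rc = tte.survival_ratio(a1, a2, n_boot=20, seed=2, mode="difference")
        assert rc.null_value == 0.0
        g1 = tte.km_estimate(a1).evaluate(rc.times)
        g2 = tte.km_estimate(a2).evaluate(rc.times)
        assert np.allclose(rc.ratio, g1 - g2, atol=1e-12)

    def test_excludes_unity_flag_consistent_with_bands(self):
        a1, a2 = self._arm(10), self._arm(11)
        rc = tte.survival_ratio(a1, a2, n_boot=200, seed=3)
        manual = (rc.ci_low > 1.0) | (rc.ci_high < 1.0)
        assert np.array_equal(rc.excludes_unity, manual)

    def test_seed_is_required(self):
        with pytest.raises(TypeError):
            tte.survival_ratio([(1, 1)], [(1, 1)], n_boot=5)
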