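"""EFS event extraction, Kaplan-Meier, LGD arithmetic, and exact tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenosynergy.bounded import BoundedValue
from xenosynergy.xenograft_survival import (EventRecord, MouseTimecourse,
                                            additivity_call, compute_lgd,
                                            cutoff_contingency, event_time,
                                            exact_logrank, km_curve,
                                            mann_whitney_exact, median_efs)


def _tc(days, values, **kw):
    return MouseTimecourse("m", "arm", days, values, **kw)


class TestEventTime:
    def test_exact_threshold_sample(self):
        ev = event_time(_tc((7, 14), (10, 25)))
        assert (ev.time, ev.event) == (14.0, True)

    def test_linear_interpolation_between_brackets(self):
        ev = event_time(_tc((7, 14), (10, 40)))
        assert ev.time == pytest.approx(7 + 7 * (25 - 10) / (40 - 10))
        # dense-resampling oracle: linear interpolation onto a fine grid
        grid = np.linspace(7, 14, 100001)
        dense = np.interp(grid, [7, 14], [10, 40])
        oracle = grid[dense >= 25][0]
        assert ev.time == pytest.approx(oracle, abs=1e-3)

    def test_first_sample_mode(self):
        ev = event_time(_tc((7, 14), (10, 40)), mode="first_sample")
        assert ev.time == 14.0

    def test_no_crossing_censors_at_followup_end(self):
        ev = event_time(_tc((7, 100), (5, 20)))
        assert (ev.time, ev.event) == (100.0, False)

    def test_morbidity_before_crossing_censors(self):
        ev = event_time(_tc((7, 14, 21), (5, 10, 60), censor_day=16.0,
                            censor_cause="morbidity"))
        assert (ev.time, ev.event) == (16.0, False)

    def test_first_sample_already_above_threshold(self):
        ev = event_time(_tc((7, 14), (30, 60)))
        assert (ev.time, ev.event) == (7.0, True)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            event_time(_tc((), ()))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=24.9), min_size=2,
                    max_size=8),
           st.floats(min_value=0.1, max_value=50.0))
    def test_raising_burden_never_delays_event(self, values, bump):
        days = tuple(7.0 * (i + 1) for i in range(len(values)))
        lo = event_time(_tc(days, tuple(values)))
        hi = event_time(_tc(days, tuple(min(v + bump, 100.0)
                                        for v in values)))
        if hi.event and lo.event:
            assert hi.time <= lo.time + 1e-9
        elif lo.event:
            pytest.fail("raising values cannot remove an event")


class TestKaplanMeier:
    def test_uniform_steps_without_censoring(self):
        recs = [EventRecord(str(i), "A", t, True) for i, t in
                enumerate([1, 2, 3, 4])]
        c = km_curve(recs)
        assert c.times == (1.0, 2.0, 3.0, 4.0)
        np.testing.assert_allclose(c.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        recs = [EventRecord(str(i), "A", t, False) for i, t in
                enumerate([10, 20, 30])]
        c = km_curve(recs)
        assert c.times == ()
        assert c(25.0) == 1.0
        assert median_efs(c) == BoundedValue(30.0, is_lower_bound=True)

    def test_matches_hand_computed_product_limit_table(self):
        # events at 1, 3, 4, 6; censored at 2 and 5
        recs = [EventRecord(str(i), "A", t, e) for i, (t, e) in enumerate(
            [(1, True), (2, False), (3, True), (4, True), (5, False),
             (6, True)])]
        c = km_curve(recs)
        assert c.times == (1.0, 3.0, 4.0, 6.0)
        np.testing.assert_allclose(
            c.survival, [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3, 0.0])
        assert median_efs(c) == BoundedValue(4.0)

    def test_curve_monotone_right_continuous_from_one(self):
        recs = [EventRecord(str(i), "A", t, i % 3 != 0) for i, t in
                enumerate([3, 1, 7, 2, 9, 5, 4])]
        c = km_curve(recs)
        assert c(0.0) == 1.0
        ts = np.linspace(0, 10, 101)
        vals = [c(t) for t in ts]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        for t in c.times:  # right-continuity: value at the step is the drop
            assert c(t) == c(t + 1e-9)

    def test_median_at_exact_half_survival(self):
        # 4 mice, 2 events: survival hits exactly 0.5 at the second event
        recs = [EventRecord(str(i), "A", t, e) for i, (t, e) in enumerate(
            [(2, True), (4, True), (9, False), (9, False)])]
        assert median_efs(km_curve(recs)) == BoundedValue(4.0)


class TestLGD:
    @pytest.mark.parametrize("treated,control,expected", [
        ("78.6", "19.7", "58.9"),
        ("8.5", "10.1", "0"),
        (">160.0", "13.2", ">146.8"),
    ])
    def test_reference_arithmetic(self, treated, control, expected):
        lgd = compute_lgd(BoundedValue.parse(treated),
                          BoundedValue.parse(control))
        exp = BoundedValue.parse(expected)
        assert lgd.value == pytest.approx(exp.value, abs=1e-9)
        assert lgd.is_lower_bound == exp.is_lower_bound

    def test_self_difference_is_zero(self):
        assert compute_lgd(BoundedValue(33.0), BoundedValue(33.0)).value == 0.0

    def test_censored_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            compute_lgd(BoundedValue(100.0), BoundedValue(50.0, True))


class TestAdditivityCall:
    def test_synergy_excess_reference_values(self):
        call = additivity_call(BoundedValue(80.0),
                               [BoundedValue(58.9), BoundedValue(7.6)])
        assert call.excess == pytest.approx(13.5)
        assert call.verdict == "synergy"
        call = additivity_call(BoundedValue(29.2),
                               [BoundedValue(22.8), BoundedValue(0.0)])
        assert call.excess == pytest.approx(6.4)
        assert call.verdict == "synergy"

    def test_exact_sum_is_additive(self):
        call = additivity_call(BoundedValue(30.0),
                               [BoundedValue(20.0), BoundedValue(10.0)])
        assert call.excess == pytest.approx(0.0)
        assert call.verdict == "additive"

    def test_deficit_is_antagonism_and_bound_propagates(self):
        call = additivity_call(BoundedValue(15.0), [BoundedValue(20.0)])
        assert call.verdict == "antagonism"
        call = additivity_call(BoundedValue(50.0, True), [BoundedValue(20.0)])
        assert call.excess_is_lower_bound


def _brute_logrank_p(arm_a, arm_b):
    """Plain-loop enumeration oracle over the score statistic |O_A - E_A|."""
    pooled = list(arm_a) + list(arm_b)
    n_a = len(arm_a)

    def stat(idx_a):
        in_a = set(idx_a)
        o_minus_e = 0.0
        for t in sorted({e.time for e in pooled if e.event}):
            at_risk = [i for i, e in enumerate(pooled) if e.time >= t]
            deaths = [i for i, e in enumerate(pooled)
                      if e.event and e.time == t]
            o_minus_e += (sum(i in in_a for i in deaths)
                          - len(deaths) * sum(i in in_a for i in at_risk)
                          / len(at_risk))
        return abs(o_minus_e)

    t_obs = stat(range(n_a))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if stat(idx) >= t_obs - 1e-9:
            count += 1
    return count / total


class TestExactLogrank:
    def test_identical_arms_p_one(self):
        a = [EventRecord(f"a{i}", "A", t, True) for i, t in
             enumerate([3, 5, 8])]
        b = [EventRecord(f"b{i}", "B", t, True) for i, t in
             enumerate([3, 5, 8])]
        assert exact_logrank(a, b) == pytest.approx(1.0)

    def test_fully_separated_arms(self):
        a = [EventRecord(f"a{i}", "A", t, True) for i, t in
             enumerate([1, 2, 3, 4])]
        b = [EventRecord(f"b{i}", "B", t, True) for i, t in
             enumerate([5, 6, 7, 8])]
        from math import comb
        assert exact_logrank(a, b) == pytest.approx(2 / comb(8, 4))

    def test_agrees_with_enumeration_oracle_with_censoring(self):
        a = [EventRecord(f"a{i}", "A", t, e) for i, (t, e) in
             enumerate([(4, True), (7, True), (11, False), (15, True),
                        (20, False)])]
        b = [EventRecord(f"b{i}", "B", t, e) for i, (t, e) in
             enumerate([(9, True), (12, True), (16, True), (22, False),
                        (25, True)])]
        assert exact_logrank(a, b) == pytest.approx(_brute_logrank_p(a, b),
                                                    abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        a = [EventRecord(f"a{i}", "A", t, True) for i, t in
             enumerate([2, 5, 7, 9, 12, 14])]
        b = [EventRecord(f"b{i}", "B", t, e) for i, (t, e) in
             enumerate([(6, True), (10, True), (13, False), (18, True),
                        (21, True), (24, False)])]
        exact = exact_logrank(a, b, max_enumeration=16)
        mc = exact_logrank(a, b, max_enumeration=4, n_mc=40_000, seed=11)
        se = np.sqrt(exact * (1 - exact) / 40_000)
        assert abs(mc - exact) < 3 * se + 2 / 40_000

    def test_label_swap_invariance(self):
        a = [EventRecord(f"a{i}", "A", t, True) for i, t in
             enumerate([2, 6, 9])]
        b = [EventRecord(f"b{i}", "B", t, True) for i, t in
             enumerate([4, 11, 13])]
        assert exact_logrank(a, b) == pytest.approx(exact_logrank(b, a))

    def test_empty_arm_rejected(self):
        a = [EventRecord("a", "A", 1.0, True)]
        with pytest.raises(ValueError):
            exact_logrank(a, [])


def _brute_mw_p(x, y):
    """Exact two-sided p by enumerating all label assignments."""
    pooled = np.array(list(x) + list(y))
    n_x = len(x)

    def u_stat(idx):
        xv = pooled[list(idx)]
        yv = np.delete(pooled, list(idx))
        return (xv[:, None] > yv[None, :]).sum()

    u_obs = u_stat(range(n_x))
    n_xy = n_x * (len(pooled) - n_x)
    dev_obs = abs(u_obs - n_xy / 2)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        total += 1
        if abs(u_stat(idx) - n_xy / 2) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_survivor_vs_dod_reference_groups(self):
        x = [56.9, 59.3, 99.7, BoundedValue(117.6, True),
             BoundedValue(146.8, True)]
        y = [22.8, 33.9, 46.2, 53.7, 58.9]
        u, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(0.0159, abs=5e-5)
        assert p == pytest.approx(4 / 252, rel=1e-12)

    def test_small_example_enumeration(self):
        _, p = mann_whitney_exact([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_label_symmetry(self):
        x, y = [3.0, 8.0, 10.0], [1.0, 6.0, 12.0]
        assert mann_whitney_exact(x, y)[1] == pytest.approx(
            mann_whitney_exact(y, x)[1])

    def test_agrees_with_enumeration_oracle(self):
        x = [4.1, 9.3, 12.7, 20.0]
        y = [2.2, 7.9, 11.5, 15.1, 30.4]
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(_brute_mw_p(x, y), rel=1e-12)

    def test_cross_group_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_exact([1.0, 2.0], [2.0, 3.0])


class TestCutoffContingency:
    def test_reference_split_at_55_days(self):
        lgds = [56.9, 59.3, 99.7, BoundedValue(117.6, True),
                BoundedValue(146.8, True), 22.8, 33.9, 46.2, 53.7, 58.9]
        outcomes = ["alive"] * 5 + ["dod"] * 5
        table, p = cutoff_contingency(lgds, outcomes, cutoff=55.0)
        assert table.tolist() == [[5, 0], [1, 4]]
        assert p == pytest.approx(0.0476, abs=5e-4)

    def test_degenerate_column_p_one(self):
        table, p = cutoff_contingency([60, 70, 80, 90], ["a", "a", "b", "b"],
                                      cutoff=55.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation(self):
        lgds = [60] * 5 + [10] * 5
        table, p = cutoff_contingency(lgds, ["a"] * 5 + ["b"] * 5, cutoff=55)
        from math import comb
        assert p == pytest.approx(2 / comb(10, 5), rel=1e-9)
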