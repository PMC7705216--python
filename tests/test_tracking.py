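"""Tests for the dynamic-range pre-phase and the four tracking procedures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clsmei import (
    DynamicRange,
    DynamicRangeConfig,
    SelectionConstraints,
    SimulatedListener,
    estimate_dynamic_range,
    run_fixed_level,
    run_mei_adaptive,
    run_slope_adaptive,
    run_urd,
)
from clsmei.tracking import read_session_log, write_session_log
from conftest import ScriptedResponder


class TestDynamicRange:
    def test_scripted_range_recovered(self):
        r = ScriptedResponder(lower=20.0, upper=90.0)
        dr = estimate_dynamic_range(r)
        assert abs(dr.lower - 20.0) <= 10.0
        assert abs(dr.upper - 90.0) <= 10.0

    def test_never_too_loud_caps_at_110(self):
        r = ScriptedResponder(lower=20.0, upper=200.0)
        dr = estimate_dynamic_range(r)
        assert dr.upper == 110.0

    def test_audible_at_zero_floors_at_0(self):
        r = ScriptedResponder(lower=-10.0, upper=90.0)
        dr = estimate_dynamic_range(r)
        assert dr.lower == 0.0

    def test_inaudible_start_recovers_via_ascending(self):
        r = ScriptedResponder(lower=75.0, upper=105.0)
        dr = estimate_dynamic_range(r)
        assert dr.lower >= 70.0
        assert dr.upper >= 100.0

    def test_never_audible_fails(self):
        with pytest.raises(ValueError):
            estimate_dynamic_range(lambda lv: 0)

    def test_degenerate_range_type_rejected(self):
        with pytest.raises(ValueError):
            DynamicRange(50.0, 50.0)


class TestFixedLevel:
    def test_full_range_is_220_trials_over_22_levels(self):
        r = ScriptedResponder(lower=0.0, upper=120.0)
        log = run_fixed_level(r, DynamicRange(5.0, 110.0), seed=0)
        levels = log.levels()
        assert len(levels) == 220
        assert len(np.unique(levels)) == 22

    def test_narrow_range_is_30_trials(self):
        r = ScriptedResponder()
        log = run_fixed_level(r, DynamicRange(50.0, 60.0), seed=1)
        assert len(log.trials) == 30
        assert set(np.unique(log.levels())) == {50.0, 55.0, 60.0}

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_sequence_constraints_hold_for_any_seed(self, seed):
        r = ScriptedResponder(lower=0.0, upper=120.0)
        log = run_fixed_level(r, DynamicRange(5.0, 110.0), seed=seed)
        diffs = np.abs(np.diff(log.levels()))
        assert diffs.max() <= 45.0
        assert diffs.min() > 0  # no immediate repeats


class TestSlopeAdaptive:
    def test_run1_levels_evenly_span(self):
        r = ScriptedResponder(lower=5.0, upper=200.0)
        log = run_slope_adaptive(r, DynamicRange(10.0, 90.0), seed=0)
        run1 = sorted(t.level for t in log.trials if t.run == 0)
        np.testing.assert_allclose(run1, np.arange(10.0, 91.0, 10.0))
        assert len(log.trials) == 45

    def test_too_loud_lowers_next_upper_limit(self):
        r = ScriptedResponder(lower=5.0, upper=85.0)  # 90 judged Too Loud
        log = run_slope_adaptive(r, DynamicRange(10.0, 90.0), seed=0)
        assert log.run_limits[0] == (10.0, 90.0)
        assert log.run_limits[1][1] == 85.0

    def test_upper_limit_never_exceeds_110(self):
        r = ScriptedResponder(lower=5.0, upper=1000.0)  # never Too Loud
        log = run_slope_adaptive(r, DynamicRange(10.0, 105.0), seed=0)
        uppers = [u for _, u in log.run_limits]
        assert max(uppers) == 110.0
        assert log.levels().max() <= 110.0

    def test_limit_steps_are_plus_minus_5(self):
        r = ScriptedResponder(lower=5.0, upper=92.0)
        log = run_slope_adaptive(r, DynamicRange(10.0, 100.0), seed=3)
        uppers = np.array([u for _, u in log.run_limits])
        assert set(np.abs(np.diff(uppers))).issubset({0.0, 5.0})


class TestMEIAdaptive:
    def test_always_45_trials_with_entropy(self, small_catalog):
        lst = SimulatedListener(small_catalog[3], seed=1)
        log = run_mei_adaptive(lst, small_catalog, DynamicRange(10.0, 100.0), seed=2)
        assert len(log.trials) == 45
        assert all(t.entropy_after is not None for t in log.trials)
        ent = [t.entropy_after for t in log.trials]
        assert ent[-1] <= np.log2(len(small_catalog))

    def test_first_level_is_midpoint(self, small_catalog):
        lst = SimulatedListener(small_catalog[0], seed=1)
        log = run_mei_adaptive(lst, small_catalog, DynamicRange(20.0, 90.0), seed=2)
        assert log.trials[0].level == 55.0

    def test_point_mass_falls_back_to_lowest_candidate(self, two_entry_catalog):
        # a modal listener matching entry 0 exactly collapses the 2-entry
        # posterior; subsequent selections tie at zero and take the tie-break
        lst = SimulatedListener(two_entry_catalog[0], mode="modal")
        c = SelectionConstraints(forbid_consecutive_repeat=True)
        log = run_mei_adaptive(lst, two_entry_catalog, DynamicRange(10.0, 100.0), c)
        ent = [t.entropy_after for t in log.trials]
        assert ent[-1] == pytest.approx(0.0, abs=1e-6)

    def test_respects_upper_limits(self, small_catalog):
        lst = SimulatedListener(small_catalog[5], seed=4)
        log = run_mei_adaptive(lst, small_catalog, DynamicRange(10.0, 100.0), seed=5)
        for t in log.trials:
            lo, hi = log.run_limits[t.run]
            assert lo - 1e-9 <= t.level <= hi + 1e-9


class TestURD:
    def test_levels_within_run_limits_and_deterministic(self):
        r = ScriptedResponder(lower=5.0, upper=95.0)
        log1 = run_urd(r, DynamicRange(10.0, 100.0), seed=9)
        r2 = ScriptedResponder(lower=5.0, upper=95.0)
        log2 = run_urd(r2, DynamicRange(10.0, 100.0), seed=9)
        assert [t.level for t in log1.trials] == [t.level for t in log2.trials]
        for t in log1.trials:
            lo, hi = log1.run_limits[t.run]
            assert lo - 1e-9 <= t.level <= hi + 1e-9

    def test_empirical_uniformity(self):
        # fix the limits by never triggering the Too Loud rule
        r = ScriptedResponder(lower=0.0, upper=1000.0)  # never Too Loud
        counts = {}
        for s in range(250):  # 250 sessions x 45 trials > 10,000 draws
            log = run_urd(r, DynamicRange(0.0, 110.0), seed=s)  # limits stay (0, 110)
            for t in log.trials:
                counts[t.level] = counts.get(t.level, 0) + 1
        obs = np.array(list(counts.values()))
        chi = stats.chisquare(obs)
        assert chi.pvalue > 0.001


class TestSessionLogIO:
    def test_csv_round_trip(self, small_catalog, tmp_path):
        lst = SimulatedListener(small_catalog[2], seed=8)
        log = run_mei_adaptive(lst, small_catalog, DynamicRange(20.0, 90.0), seed=8)
        path = tmp_path / "log.csv"
        write_session_log(log, path)
        back = read_session_log(path)
        assert [t.level for t in back.trials] == [t.level for t in log.trials]
        assert [t.response_cu for t in back.trials] == [t.response_cu for t in log.trials]
        assert back.procedure == "mei"
        assert back.dynamic_range == log.dynamic_range
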