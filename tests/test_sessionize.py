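import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrcollab import sessionize
from ehrcollab.audit_log import events_from_records
from ehrcollab.sessionize import (
    KneeNotFoundError,
    build_intervals,
    discrete_curvature,
    estimate_cutoff,
    flag_workdays,
    interval_count_curve,
    knee_point,
)
from oracles import naive_intervals, random_event_stream


class TestBuildIntervals:
    def test_between_task_gap_splits_first_stream(self, example_events):
        """HCW A's 203 s pause splits six events into a 2-event and a
        4-event interval at a 120 s cutoff."""
        iv = build_intervals(example_events, 120)
        a = iv[iv["hcw_id"] == "A"].reset_index(drop=True)
        assert len(a) == 2
        assert a.loc[0, "start"] == pd.Timestamp("2020-04-05 02:14:25")
        assert a.loc[0, "stop"] == pd.Timestamp("2020-04-05 02:15:00")
        assert a.loc[0, "n_events"] == 2
        assert a.loc[1, "start"] == pd.Timestamp("2020-04-05 02:18:23")
        assert a.loc[1, "stop"] == pd.Timestamp("2020-04-05 02:22:23")
        assert a.loc[1, "n_events"] == 4

    def test_evenly_spaced_stream_stays_whole(self, example_events):
        """HCW B's gaps (104..114 s) all sit under the cutoff: one 480 s
        interval of six events."""
        iv = build_intervals(example_events, 120)
        b = iv[iv["hcw_id"] == "B"].reset_index(drop=True)
        assert len(b) == 1
        assert b.loc[0, "duration_s"] == 480
        assert b.loc[0, "n_events"] == 6

    def test_single_event_yields_zero_duration(self):
        ev = events_from_records([("H", "P", "ACT", "2020-01-01 08:00:00")])
        iv = build_intervals(ev, 60)
        assert len(iv) == 1
        assert iv.loc[0, "duration_s"] == 0

    def test_gap_equal_to_cutoff_does_not_split(self):
        ev = events_from_records(
            [
                ("H", "P", "A", "2020-01-01 08:00:00"),
                ("H", "P", "B", "2020-01-01 08:02:00"),
            ]
        )
        assert len(build_intervals(ev, 120)) == 1
        assert len(build_intervals(ev, 119)) == 2

    def test_unsorted_input_rejected(self, example_events):
        shuffled = example_events.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            build_intervals(shuffled, 120)

    def test_matches_naive_scan_on_random_streams(self, rng):
        for _ in range(25):
            ev = random_event_stream(rng, int(rng.integers(5, 400)))
            cutoff = float(rng.uniform(5, 600))
            got = build_intervals(ev, cutoff, collect_actions=False)
            got_tuples = sorted(
                zip(got["hcw_id"], got["patient_id"], got["start"], got["stop"],
                    got["n_events"])
            )
            assert got_tuples == naive_intervals(ev, cutoff)

    def test_partition_and_monotonicity_across_cutoffs(self, rng):
        ev = random_event_stream(rng, 600)
        prev_count, prev_dur = np.inf, 0.0
        for cutoff in (5, 30, 120, 600, 3600):
            iv = build_intervals(ev, cutoff, collect_actions=False)
            assert iv["n_events"].sum() == len(ev)
            assert len(iv) <= prev_count
            assert iv["duration_s"].sum() >= prev_dur - 1e-9
            prev_count, prev_dur = len(iv), iv["duration_s"].sum()

    def test_count_curve_equals_full_builds(self, rng):
        ev = random_event_stream(rng, 300)
        cands = np.arange(10.0, 900.0, 37.0)
        fast = interval_count_curve(ev, cands)
        slow = [len(build_intervals(ev, c, collect_actions=False)) for c in cands]
        assert list(fast) == slow


class TestKneePoint:
    @staticmethod
    def _piecewise(x, breakpoint=2.0, s1=-10.0, s2=-0.1):
        y = np.where(
            x <= breakpoint, 100 + s1 * x, 100 + s1 * breakpoint + s2 * (x - breakpoint)
        )
        return y

    def test_piecewise_linear_knee_at_breakpoint(self):
        x = np.arange(0, 10.01, 0.25)
        y = self._piecewise(x)
        assert knee_point(x, y, smoothing=1) == 2.0
        # the discrete-curvature oracle localizes the corner to within one
        # grid step (the steep flank suppresses curvature at the sample
        # exactly on the breakpoint)
        kappa = discrete_curvature(x, y)
        assert abs(x[np.argmax(np.abs(kappa))] - 2.0) <= 0.25

    def test_pure_line_has_no_knee(self):
        x = np.arange(0, 10.0, 0.5)
        with pytest.raises(KneeNotFoundError):
            knee_point(x, 50 - x, smoothing=1)

    def test_flat_curve_has_no_knee(self):
        x = np.arange(0, 10.0, 0.5)
        with pytest.raises(KneeNotFoundError):
            knee_point(x, np.full_like(x, 7.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            knee_point([1, 2, 3], [3, 2, 1])

    def test_curvature_of_parabola_at_origin(self):
        """For f(x)=x^2 the closed-form curvature at 0 is f''/(1+f'^2)^1.5 = 2."""
        x = np.arange(-2, 2.01, 0.01)
        kappa = discrete_curvature(x, x**2)
        assert kappa[np.argmin(np.abs(x))] == pytest.approx(2.0, abs=1e-3)

    @given(
        ax=st.floats(0.1, 50),
        bx=st.floats(-100, 100),
        ay=st.floats(0.1, 50),
        by=st.floats(-100, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, ax, bx, ay, by):
        x = np.arange(0, 10.01, 0.25)
        y = self._piecewise(x)
        base = knee_point(x, y, smoothing=1)
        scaled = knee_point(ax * x + bx, ay * y + by, smoothing=1)
        assert scaled == pytest.approx(ax * base + bx, rel=1e-9, abs=1e-9)


class TestEstimateCutoff:
    def test_bimodal_gaps_put_knee_between_scales(self, rng):
        """Within-burst ~Exp(30 s) and between-burst ~Exp(1200 s) gaps place
        the interval-count knee between the gap scales."""
        records = []
        base = pd.Timestamp("2020-02-03")
        for h in range(60):
            t = float(rng.uniform(0, 3600))
            for _ in range(30):
                n = 2 + int(rng.poisson(4))
                for _ in range(n):
                    records.append((f"H{h}", "P0", "ACT", base + pd.Timedelta(seconds=t)))
                    t += float(rng.exponential(30))
                t += float(rng.exponential(1200))
        ev = events_from_records(records)
        cutoff = estimate_cutoff(ev, np.arange(10.0, 1801.0, 10.0))
        assert 60 <= cutoff <= 300

    def test_all_gaps_tiny_means_flat_curve(self):
        ev = events_from_records(
            [("H", "P", "A", f"2020-01-01 08:00:{s:02d}") for s in range(0, 40, 4)]
        )
        with pytest.raises(KneeNotFoundError):
            estimate_cutoff(ev, np.arange(10.0, 1801.0, 10.0))

    def test_two_gap_values_bracketed(self, rng):
        records = []
        t = pd.Timestamp("2020-01-01")
        for i in range(120):
            records.append(("H", "P", "A", t))
            t += pd.Timedelta(seconds=5 if i % 4 else 500)
        ev = events_from_records(records)
        cutoff = estimate_cutoff(ev, np.arange(2.0, 600.0, 2.0))
        assert 5 < cutoff < 500


class TestWorkdays:
    def test_single_long_interval_is_active(self):
        iv = _intervals([("H", "2020-01-06 09:00:00", "2020-01-06 09:20:00")])
        wd = flag_workdays(iv, 15)
        assert wd.loc[0, "active"]

    def test_short_fragments_are_inactive(self):
        iv = _intervals(
            [
                ("H", "2020-01-06 09:00:00", "2020-01-06 09:04:00"),
                ("H", "2020-01-06 11:00:00", "2020-01-06 11:04:00"),
                ("H", "2020-01-06 15:00:00", "2020-01-06 15:04:00"),
            ]
        )
        wd = flag_workdays(iv, 15)
        assert len(wd) == 1
        assert wd.loc[0, "ehr_time_min"] == pytest.approx(12.0)
        assert not wd.loc[0, "active"]

    def test_midnight_crossing_interval_split_between_days(self):
        iv = _intervals([("H", "2020-01-06 23:50:00", "2020-01-07 00:10:00")])
        wd = flag_workdays(iv, 15)
        assert len(wd) == 2
        assert list(wd["ehr_time_min"]) == pytest.approx([10.0, 10.0])
        assert not wd["active"].any()


def _intervals(rows):
    df = pd.DataFrame(rows, columns=["hcw_id", "start", "stop"])
    df["patient_id"] = "P"
    df["start"] = pd.to_datetime(df["start"])
    df["stop"] = pd.to_datetime(df["stop"])
    df["duration_s"] = (df["stop"] - df["start"]).dt.total_seconds()
    df["n_events"] = 2
    return df
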