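"""Simulator determinism, statistical structure and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

import sleepscratch as ss
from sleepscratch.simulate import _schedule
from sleepscratch.tso import arm_angle_series, smoothed_angle_change


class TestDeterminism:
    def test_same_seed_bit_identical(self, sim_cfg, night):
        again = ss.simulate_recording(sim_cfg, 0)
        np.testing.assert_array_equal(
            night.left.accel.to_numpy(), again.left.accel.to_numpy()
        )
        np.testing.assert_array_equal(
            night.left.temp.to_numpy(), again.left.temp.to_numpy()
        )
        assert night.tso.start == again.tso.start
        assert len(night.events) == len(again.events)

    def test_distinct_subjects_distinct_data(self, sim_cfg, night):
        other = ss.simulate_recording(sim_cfg, 1)
        assert not np.array_equal(
            night.left.accel.to_numpy()[:2000], other.left.accel.to_numpy()[:2000]
        )

    def test_wrists_differ_but_share_schedule(self, night):
        assert not np.array_equal(
            night.left.accel.to_numpy()[:2000], night.right.accel.to_numpy()[:2000]
        )
        assert night.left.accel.index[0] == night.right.accel.index[0]


class TestBoutStatistics:
    def test_zero_scratch_rate_means_no_scratch_events(self):
        cfg = ss.SimConfig(seed=5, scratch_bout_rate=0.0)
        night = ss.simulate_recording(cfg, 0)
        assert not any(ev.behavior == "scratch" for ev in night.events)

    def test_total_bout_time_matches_expectation(self):
        # law of expectation over 100 scheduled nights: total scratch time
        # ~ rate x mean duration x night length (schedules only; no signal)
        cfg = ss.SimConfig(seed=9)
        total, hours = 0.0, 0.0
        for sid in range(100):
            sched = _schedule(cfg, sid)
            hours += (sched["night_end"] - sched["night_start"]).total_seconds() / 3600
            total += sum(
                ev.duration_s for ev in sched["events"] if ev.behavior == "scratch"
            )
        # lognormal(mu=log 10, sigma=0.5) mean = 10 * exp(0.125), minus a
        # small loss from overlap rejection
        expected = cfg.scratch_bout_rate * hours * 10.0 * np.exp(0.125)
        assert total == pytest.approx(expected, rel=0.10)

    def test_annotations_align_with_truth_window_labels(self, night):
        starts = pd.date_range(night.tso.start, night.tso.end, freq="3s")[:-1]
        labels = night.true_window_labels(starts, wrist="left")
        # every fully-covered scratch event must produce scratch-labeled windows
        for ev in night.events:
            if ev.behavior != "scratch" or ev.hand not in ("left", "both"):
                continue
            if ev.duration_s < 6:
                continue
            inside = (starts >= ev.start) & (starts + pd.Timedelta(seconds=3) <= ev.end)
            if inside.any():
                assert (labels[np.asarray(inside)] == "scratch").all()

    def test_events_lie_inside_night(self, night):
        for ev in night.events:
            assert ev.start >= night.tso.start
            assert ev.end <= night.tso.end + pd.Timedelta(seconds=1)


class TestSignalStructure:
    def test_still_worn_night_angle_metric_below_threshold(self):
        cfg = ss.SimConfig(
            seed=13, scratch_bout_rate=0.0, restless_bout_rate=0.0, night_wake_bouts=0
        )
        night = ss.simulate_recording(cfg, 0)
        day = [d for d in ss.slice_days(night.left) if d.valid][0]
        angle = arm_angle_series(day.accel, day.accel_rate)
        sm = smoothed_angle_change(angle)
        in_night = (sm.index >= night.tso.start) & (sm.index < night.tso.end)
        frac_below = (sm[in_night] < 0.1).mean()
        assert frac_below > 0.95

    def test_scratch_windows_faster_and_jerkier_than_restless(self, labeled_windows):
        _, X, y, _ = labeled_windows
        names = list(ss.FEATURE_NAMES)
        df = pd.DataFrame(X, columns=names)
        mean_scratch = df[y == "scratch"].mean()
        mean_restless = df[y == "restless"].mean()
        assert mean_scratch["svm_mean_cross_rate"] > mean_restless["svm_mean_cross_rate"]
        assert mean_scratch["svm_dominant_freq"] > mean_restless["svm_dominant_freq"]
        assert mean_scratch["svm_jerk_ratio"] > mean_restless["svm_jerk_ratio"]
        # scratch is less smooth: SPARC magnitude larger (more negative)
        assert mean_scratch["svm_sparc"] < mean_restless["svm_sparc"]

    def test_temperature_tracks_wear_state(self):
        cfg = ss.SimConfig(seed=4, nonwear_episodes=((2.0, 60.0),))
        night = ss.simulate_recording(cfg, 0)
        temp = night.left.temp["temp_c"]
        t0 = night.left.accel.index[0]
        during = temp[(temp.index >= t0 + pd.Timedelta(hours=2.5)) & (temp.index < t0 + pd.Timedelta(hours=2.9))]
        outside = temp[temp.index < t0 + pd.Timedelta(hours=1.5)]
        assert during.mean() < 25.0
        assert outside.mean() > 30.0


class TestCohortDataset:
    def test_cohort_round_trips_through_readers(self, cohort_dir, short_cfg):
        night = ss.simulate_recording(short_cfg, 0)
        rec = ss.read_recording(
            cohort_dir / "subject_00" / "left_accel.csv",
            cohort_dir / "subject_00" / "left_temp.csv",
            wrist="left",
        )
        assert len(rec.accel) == len(night.left.accel)
        np.testing.assert_allclose(
            rec.accel.to_numpy(), night.left.accel.to_numpy(), atol=1e-5
        )
        assert rec.accel_rate == pytest.approx(short_cfg.fs, rel=1e-6)
        events = ss.io.read_annotations(cohort_dir / "subject_00" / "annotations.csv")
        assert [e.behavior for e in events] == [e.behavior for e in night.events]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ss.SimConfig(scratch_band=(5.0, 2.5))
        with pytest.raises(ValueError):
            ss.SimConfig(wear_temp=25.0, nonwear_temp=25.0)
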