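"""Shared fixtures: simulated nights, labeled window sets, tiny cohorts.

Expensive simulations are session-scoped so the whole suite reuses them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sleepscratch as ss


@pytest.fixture(scope="session")
def sim_cfg() -> ss.SimConfig:
    return ss.SimConfig(seed=7)


@pytest.fixture(scope="session")
def night(sim_cfg):
    return ss.simulate_recording(sim_cfg, 0)


@pytest.fixture(scope="session")
def valid_day(night):
    return [d for d in ss.slice_days(night.left) if d.valid][0]


@pytest.fixture(scope="session")
def detected_tso(valid_day):
    tso = ss.detect_tso(valid_day)
    assert tso is not None
    return tso


@pytest.fixture(scope="session")
def labeled_windows(sim_cfg):
    """(raw windows, feature matrix, labels, subject ids) for 4 subjects."""
    Xraw, y, subj = ss.simulate_labeled_windows(
        sim_cfg, n_subjects=4, windows_per_subject=60
    )
    X = ss.WindowFeatureExtractor().transform(Xraw)
    return Xraw, X, y, subj


@pytest.fixture(scope="session")
def scratch_model(labeled_windows):
    _, X, y, _ = labeled_windows
    return ss.train_scratch_classifier(X, y, seed=11)


@pytest.fixture(scope="session")
def short_cfg() -> ss.SimConfig:
    """A shorter evening-to-night recording for IO-heavy tests."""
    return ss.SimConfig(
        seed=3,
        rec_start="20:00",
        rec_hours=8.0,
        night_start="22:00",
        night_end="03:30",
        schedule_jitter_min=5.0,
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, short_cfg):
    out = tmp_path_factory.mktemp("cohort")
    ss.simulate_cohort(short_cfg, n=2, out_dir=out)
    return out


def make_active_recording(
    hours: float = 7.0, fs: float = 20.0, seed: int = 0
) -> ss.RawRecording:
    """A recording of continuous waking activity (no still period)."""
    rng = np.random.default_rng(seed)
    n = int(hours * 3600 * fs)
    t = np.arange(n) / fs
    key_t = np.arange(0.0, hours * 3600 + 60, 60.0)
    key_o = rng.normal(size=(len(key_t), 3))
    key_o /= np.linalg.norm(key_o, axis=1, keepdims=True)
    g = np.column_stack([np.interp(t, key_t, key_o[:, i]) for i in range(3)])
    g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-9)
    accel = g + rng.normal(0, 0.1, size=(n, 3))
    index = pd.Timestamp("2024-03-01 12:30:00") + pd.to_timedelta(t, unit="s")
    df = pd.DataFrame(accel, index=index, columns=["x", "y", "z"])
    df.index.name = "timestamp"
    temp_idx = pd.date_range(index[0], index[-1], freq="3s")
    temp = pd.DataFrame({"temp_c": np.full(len(temp_idx), 33.0)}, index=temp_idx)
    temp.index.name = "timestamp"
    return ss.RawRecording(wrist="left", accel=df, temp=temp, accel_rate=fs)
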