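"""End-to-end processing: raw recording -> nightly endpoint tables.

The hierarchical flow per wrist and 24-h day: resample to the analysis
rate, slice noon-to-noon, detect wear from temperature, detect the total
sleep opportunity (TSO) from arm-angle dynamics, score 1-min sleep/wake
epochs inside the TSO (with Webster rescoring), gate 3-s windows by hand
movement, classify gated windows with the scratch model, and summarise the
night into digital endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .endpoints import (
    NightEndpoints,
    exploratory_sleep_endpoints,
    scratch_endpoints,
    sleep_endpoints,
)
from .features import WindowFeatureExtractor, detect_hand_movement
from .io import DaySegment, RawRecording, read_annotations, read_recording, resample_accel, segment_annotation, slice_days
from .scratch import NON_SCRATCH, ScratchClassifier, predict_windows
from .sleepwake import ColeKripkeScorer, activity_series, webster_rescore
from .tso import TSODetector, TSOWindow

log = logging.getLogger("sleepscratch")


@dataclass
class NightResult:
    """Everything computed for one wrist-night."""

    endpoints: NightEndpoints
    epochs: pd.DataFrame | None = None
    windows: pd.DataFrame | None = None
    tso: TSOWindow | None = None


def extract_windows(
    accel: pd.DataFrame, tso: TSOWindow, rate: float, window_s: float = 3.0
) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Non-overlapping fixed-length raw windows tiling the TSO window.

    Returns a (n_windows, samples, 3) array and the window start times.
    Windows with missing samples (gaps) are excluded.
    """
    ns = int(round(window_s * rate))
    n_win = int((tso.end - tso.start).total_seconds() // window_s)
    idx = accel.index.view("int64")
    arr = accel[["x", "y", "z"]].to_numpy(dtype=float)
    t0 = tso.start.value
    step_ns = int(window_s * 1e9)
    outs, starts = [], []
    for i in range(n_win):
        lo = np.searchsorted(idx, t0 + i * step_ns, side="left")
        hi = np.searchsorted(idx, t0 + (i + 1) * step_ns, side="left")
        if hi - lo == ns:
            outs.append(arr[lo:hi])
            starts.append(pd.Timestamp(t0 + i * step_ns))
    if not outs:
        return np.empty((0, ns, 3)), pd.DatetimeIndex([])
    return np.stack(outs), pd.DatetimeIndex(starts)


def process_day(
    day: DaySegment,
    model: ScratchClassifier | None = None,
    config: PipelineConfig | None = None,
) -> NightResult:
    """Run the full hierarchy on one valid 24-h day segment."""
    cfg = config or PipelineConfig()
    night_id = str(day.day_start.date())
    ep = NightEndpoints(night_id=night_id, wrist=day.wrist)
    if not day.valid:
        ep.reason = "invalid-day"
        return NightResult(endpoints=ep)

    detector = TSODetector(
        threshold_floor=cfg.tso_threshold_floor,
        percentile=cfg.tso_percentile,
        min_block_min=cfg.tso_min_block_min,
        merge_gap_min=cfg.tso_merge_gap_min,
        wear_threshold=cfg.wear_threshold,
    )
    tso = detector.detect(day)
    if tso is None:
        ep.reason = "no-tso"
        log.info("%s %s: no TSO window found", night_id, day.wrist)
        return NightResult(endpoints=ep)
    log.info(
        "%s %s: TSO %s -> %s (%.0f min)",
        night_id, day.wrist, tso.start, tso.end, tso.duration_min,
    )

    # sleep/wake scoring inside the TSO
    activity = activity_series(
        day.accel, tso, day.accel_rate,
        epoch_s=cfg.epoch_s, noise_var=cfg.activity_noise_var,
    )
    scorer = ColeKripkeScorer(weights=cfg.ck_weights, scale=cfg.ck_scale)
    raw_states = pd.Series(scorer.predict(activity), index=activity.index)
    states = webster_rescore(raw_states, rules=cfg.webster_rules)
    epochs = pd.DataFrame(
        {
            "epoch_len": cfg.epoch_s,
            "activity": activity,
            "state_raw": raw_states,
            "state_rescored": states,
        }
    )
    epochs.index.name = "epoch_start"

    tso_min, tst, pta = sleep_endpoints(states, tso)
    nwb, waso, sol = exploratory_sleep_endpoints(states)
    ep.tso_minutes, ep.tst_minutes, ep.pta_percent = tso_min, tst, pta
    ep.nwb, ep.waso_minutes, ep.sol_minutes = nwb, waso, sol

    # 3-s windows: hand-movement gate, then scratch classification
    raw_windows, starts = extract_windows(day.accel, tso, day.accel_rate, cfg.window_s)
    moving = np.array(
        [
            detect_hand_movement(
                w, fs=day.accel_rate,
                cov_threshold=cfg.cov_threshold,
                subwindow_s=cfg.cov_subwindow_s,
            )
            for w in raw_windows
        ],
        dtype=bool,
    )
    log.info(
        "%s %s: %d windows, %d with hand movement",
        night_id, day.wrist, len(raw_windows), int(moving.sum()),
    )
    if model is not None and len(raw_windows):
        extractor = WindowFeatureExtractor(fs=day.accel_rate, cutoff=cfg.hp_cutoff_hz)
        feats = np.zeros((len(raw_windows), len(extractor.get_feature_names_out())))
        if moving.any():
            feats[moving] = extractor.transform(raw_windows[moving])
        windows = predict_windows(model, feats, moving, threshold=cfg.predict_threshold)
    else:
        windows = pd.DataFrame(
            {
                "hand_moving": moving,
                "pred": np.full(len(raw_windows), NON_SCRATCH, dtype=object),
                "probability": np.full(len(raw_windows), np.nan),
            }
        )
        if model is None:
            ep.reason = "no-model" if ep.reason == "" else ep.reason
    windows.insert(0, "window_start", starts)
    windows.insert(1, "wrist", day.wrist)
    if model is not None:
        events, duration = scratch_endpoints(windows, window_s=cfg.window_s)
        ep.scratch_events, ep.scratch_duration_minutes = events, duration
    return NightResult(endpoints=ep, epochs=epochs, windows=windows, tso=tso)


def process_recording(
    rec: RawRecording,
    model: ScratchClassifier | None = None,
    config: PipelineConfig | None = None,
) -> list[NightResult]:
    """Slice a recording into days and process each valid day."""
    cfg = config or PipelineConfig()
    if rec.accel_rate > cfg.target_rate * (1 + 1e-9):
        rec = resample_accel(rec, cfg.target_rate)
    results = []
    for day in slice_days(rec, min_hours=cfg.min_day_hours):
        if not day.valid:
            log.info(
                "%s %s: skipped (%.1f h recorded < %.1f h required)",
                day.day_start.date(), day.wrist, day.recorded_hours, cfg.min_day_hours,
            )
            continue
        results.append(process_day(day, model=model, config=cfg))
    return results


def endpoints_table(results: list[NightResult]) -> pd.DataFrame:
    """Nightly endpoint rows (one per wrist-night) as a DataFrame."""
    return pd.DataFrame([r.endpoints.as_row() for r in results])


def build_training_set(
    data_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble labeled training windows from a cohort dataset directory.

    Expects the layout written by the simulator (``subject_XX`` directories
    with per-wrist accel CSVs and an ``annotations.csv``).  Annotated events
    of at least the window length are tiled with the training overlap; raw
    windows are cut from the wrist(s) each annotation names.

    Returns (raw windows, labels, subject ids).
    """
    cfg = config or PipelineConfig()
    data_dir = Path(data_dir)
    subdirs = sorted(d for d in data_dir.iterdir() if d.is_dir() and d.name.startswith("subject"))
    if not subdirs:
        raise FileNotFoundError(f"no subject_* directories under {data_dir}")
    ns = int(round(cfg.window_s * cfg.target_rate))
    X, y, subjects = [], [], []
    for sub in subdirs:
        sid = sub.name
        events = read_annotations(sub / "annotations.csv")
        accel = {}
        for wrist in ("left", "right"):
            path = sub / f"{wrist}_accel.csv"
            if path.exists():
                rec = read_recording(path, wrist=wrist)
                if rec.accel_rate > cfg.target_rate * (1 + 1e-9):
                    rec = resample_accel(rec, cfg.target_rate)
                accel[wrist] = rec.accel
        for ev in events:
            wrists = ("left", "right") if ev.hand == "both" else (ev.hand,)
            for ws, we in segment_annotation(ev, cfg.window_s, cfg.train_overlap):
                for wrist in wrists:
                    if wrist not in accel:
                        continue
                    df = accel[wrist]
                    idx = df.index.view("int64")
                    lo = np.searchsorted(idx, ws.value, side="left")
                    if lo + ns <= len(df):
                        X.append(df.iloc[lo : lo + ns][["x", "y", "z"]].to_numpy(dtype=float))
                        y.append(ev.behavior)
                        subjects.append(sid)
    if not X:
        raise ValueError(f"no usable training windows found under {data_dir}")
    return np.asarray(X), np.asarray(y), np.asarray(subjects)
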