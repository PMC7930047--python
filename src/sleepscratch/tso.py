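"""Nightly total-sleep-opportunity (TSO) detection from arm-angle dynamics.

The detector follows the arm-angle heuristic used for sleep-window detection
in wrist actigraphy: the wrist's elevation angle relative to the horizontal
plane is computed from the gravity component of the acceleration signal on a
5-s grid; sustained periods where the absolute successive change in angle
stays below a per-day threshold are candidate sleep-opportunity periods, and
the longest worn candidate of each 24-h day is the TSO window.

The per-day threshold is ``max(threshold_floor, P25)`` where ``P25`` is the
25th percentile of the 5-min-median-smoothed angle change over on-body
samples and the floor defaults to 0.1 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import DaySegment
from .wear import METRIC_EPOCH_S, preprocess_temperature


@dataclass
class TSOWindow:
    """The detected nightly sleep-opportunity interval ``[start, end)``."""

    start: pd.Timestamp
    end: pd.Timestamp
    source_day: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TSO end must follow start")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def arm_angle_series(accel: pd.DataFrame, rate: float) -> pd.Series:
    """Wrist elevation angle (degrees) on a 5-s grid.

    Each axis is smoothed with a 5-s rolling median and averaged over
    consecutive 5-s blocks; the angle of the resulting gravity estimate
    relative to the horizontal plane is
    ``atan2(z, sqrt(x^2 + y^2)) * 180 / pi``, in [-90, 90].
    """
    if len(accel) == 0:
        raise ValueError("empty acceleration stream")
    win = max(1, int(round(METRIC_EPOCH_S * rate)))
    med = accel[["x", "y", "z"]].rolling(win, min_periods=1).median()
    blk = med.resample(f"{METRIC_EPOCH_S}s").mean().dropna(how="all")
    x, y, z = (blk[c].to_numpy(dtype=float) for c in "xyz")
    mag = np.sqrt(x * x + y * y + z * z)
    if np.any(mag < 1e-6):
        raise ValueError("zero-magnitude acceleration sample: arm angle undefined")
    angle = np.degrees(np.arctan2(z, np.hypot(x, y)))
    out = pd.Series(angle, index=blk.index, name="arm_angle")
    out.index.name = "epoch_start"
    return out


def smoothed_angle_change(angle: pd.Series) -> pd.Series:
    """5-min rolling median of the absolute successive angle change."""
    change = angle.diff().abs()
    if len(change):
        change.iloc[0] = 0.0
    sm = change.rolling(60, min_periods=1, center=True).median()
    return sm.rename("smoothed_change")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


class TSODetector(BaseEstimator):
    """Detect the nightly total sleep opportunity of a 24-h day segment.

    Parameters
    ----------
    threshold_floor : float, default 0.1
        Lower bound (degrees) on the per-day angle-change threshold.
    percentile : float, default 25
        Percentile of the smoothed angle change (on-body samples only)
        used for the adaptive threshold.
    min_block_min : float, default 30
        Candidate runs shorter than this are dropped.
    merge_gap_min : float, default 30
        Runs separated by a gap shorter than this are merged.
    wear_threshold : float, default 25.0
        Processed temperature (Celsius) below which the device counts as
        off-body; candidates containing any off-body sample are excluded.
    """

    def __init__(
        self,
        threshold_floor: float = 0.1,
        percentile: float = 25.0,
        min_block_min: float = 30.0,
        merge_gap_min: float = 30.0,
        wear_threshold: float = 25.0,
    ):
        self.threshold_floor = threshold_floor
        self.percentile = percentile
        self.min_block_min = min_block_min
        self.merge_gap_min = merge_gap_min
        self.wear_threshold = wear_threshold

    def detect(self, day: DaySegment) -> TSOWindow | None:
        """Return the day's TSO window, or None when no candidate survives."""
        if not day.valid:
            return None
        angle = arm_angle_series(day.accel, day.accel_rate)
        if len(angle) < 2:
            return None
        smoothed = smoothed_angle_change(angle)
        if day.temp is not None and len(day.temp):
            wear = preprocess_temperature(day.temp, self.wear_threshold)
            worn = (
                wear["worn"]
                .reindex(angle.index, method="nearest")
                .fillna(False)
                .to_numpy(dtype=bool)
            )
        else:
            worn = np.ones(len(angle), dtype=bool)
        vals = smoothed.to_numpy(dtype=float)
        onbody = vals[worn]
        if onbody.size:
            threshold = max(self.threshold_floor, float(np.percentile(onbody, self.percentile)))
        else:
            threshold = self.threshold_floor
        below = vals < threshold

        epoch = METRIC_EPOCH_S
        merge_gap = int(round(self.merge_gap_min * 60 / epoch))
        min_len = int(round(self.min_block_min * 60 / epoch))

        # drop sub-minimum runs first, then bridge short gaps between the
        # surviving blocks: scattered below-threshold noise on an active day
        # must not chain into a spurious candidate
        runs = [(s, e) for s, e in _runs(below) if e - s >= min_len]
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        candidates = [(s, e) for s, e in merged]
        # exclude candidates containing any off-body sample
        candidates = [(s, e) for s, e in candidates if worn[s:e].all()]
        if not candidates:
            return None
        s, e = max(candidates, key=lambda se: se[1] - se[0])
        start = angle.index[s]
        end = angle.index[e - 1] + pd.Timedelta(seconds=epoch)
        return TSOWindow(start=start, end=end, source_day=day.day_start)


def detect_tso(
    day: DaySegment,
    threshold_floor: float = 0.1,
    min_block_min: float = 30.0,
    merge_gap_min: float = 30.0,
    wear_threshold: float = 25.0,
) -> TSOWindow | None:
    """Functional wrapper around :class:`TSODetector`."""
    det = TSODetector(
        threshold_floor=threshold_floor,
        min_block_min=min_block_min,
        merge_gap_min=merge_gap_min,
        wear_threshold=wear_threshold,
    )
    return det.detect(day)
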