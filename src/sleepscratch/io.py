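"""Reading, writing and slicing of wrist-sensor time series.

The package consumes plain CSV tables with ISO-8601 timestamps:

* acceleration  -- ``timestamp,x,y,z``      (units: g)
* temperature   -- ``timestamp,temp_c``     (units: degrees Celsius)
* annotations   -- ``start,end,behavior,hand,severity``
* 30-s epochs   -- ``epoch_start,state``

Timestamps are interpreted as the participant's local clock time; both naive
and timezone-aware stamps are accepted.  Day boundaries ("noon to noon") are
taken on the clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

BEHAVIORS = ("scratch", "restless")
HANDS = ("left", "right", "both")
SEVERITIES = ("mild", "moderate", "severe", "none")
WRISTS = ("left", "right")


class FormatError(ValueError):
    """Raised when an input table does not match the documented CSV dialect."""


class DataError(ValueError):
    """Raised when a table parses but violates a data invariant."""


@dataclass
class RawRecording:
    """One wrist's raw sensor streams.

    Parameters
    ----------
    wrist : {"left", "right"}
    accel : DataFrame with a DatetimeIndex and columns ``x, y, z`` in g.
    temp : DataFrame with a DatetimeIndex and column ``temp_c`` in Celsius,
        or None when no temperature stream is available.
    accel_rate, temp_rate : sampling rates in Hz (inferred from the median
        inter-sample interval when read from file).
    """

    wrist: str
    accel: pd.DataFrame
    temp: pd.DataFrame | None = None
    accel_rate: float = float("nan")
    temp_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.wrist not in WRISTS:
            raise ValueError(f"wrist must be one of {WRISTS}, got {self.wrist!r}")
        _check_stream(self.accel, ("x", "y", "z"), "accel")
        if self.temp is not None and len(self.temp):
            _check_stream(self.temp, ("temp_c",), "temp")
        if np.isnan(self.accel_rate) and len(self.accel) > 1:
            self.accel_rate = infer_rate(self.accel.index)
        if (
            self.temp is not None
            and np.isnan(self.temp_rate)
            and len(self.temp) > 1
        ):
            self.temp_rate = infer_rate(self.temp.index)

    @property
    def start(self) -> pd.Timestamp:
        return self.accel.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.accel.index[-1]


@dataclass(frozen=True)
class AnnotationEvent:
    """A human-annotated behavior interval (video review)."""

    start: pd.Timestamp
    end: pd.Timestamp
    behavior: str
    hand: str = "both"
    severity: str = "none"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError("annotation end must follow start")
        if self.behavior not in BEHAVIORS:
            raise DataError(f"behavior must be one of {BEHAVIORS}")
        if self.hand not in HANDS:
            raise DataError(f"hand must be one of {HANDS}")
        if self.severity not in SEVERITIES:
            raise DataError(f"severity must be one of {SEVERITIES}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class DaySegment:
    """One noon-to-noon 24-h slice of a recording.

    ``valid`` is True when at least ``min_hours`` of data were recorded
    inside the slice; invalid segments are excluded from downstream analysis.
    """

    day_start: pd.Timestamp
    accel: pd.DataFrame
    temp: pd.DataFrame | None
    recorded_hours: float
    valid: bool
    wrist: str = "left"
    accel_rate: float = float("nan")

    @property
    def day_end(self) -> pd.Timestamp:
        return self.day_start + pd.Timedelta(hours=24)


def _check_stream(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{name} table is missing columns {missing}")
    if not isinstance(df.index, pd.DatetimeIndex):
        raise FormatError(f"{name} table must be indexed by timestamp")
    if len(df) > 1 and not df.index.is_monotonic_increasing:
        raise DataError(f"{name} timestamps are not sorted")
    if len(df) > 1 and df.index.has_duplicates:
        raise DataError(f"{name} timestamps contain duplicates")
    vals = df[list(columns)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise DataError(f"{name} stream contains non-finite values")


def infer_rate(index: pd.DatetimeIndex) -> float:
    """Sampling rate in Hz from the median inter-sample interval."""
    if len(index) < 2:
        raise DataError("need at least two samples to infer a sampling rate")
    dt = np.median(np.diff(index.view("int64"))) / 1e9
    if dt <= 0:
        raise DataError("non-increasing timestamps")
    return 1.0 / dt


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    ts_col = required[0]
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(f"{path} is missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path} has a header but no rows")
    df[ts_col] = pd.to_datetime(df[ts_col], format="ISO8601")
    df = df.set_index(ts_col)
    df.index.name = "timestamp"
    if len(df) > 1 and not df.index.is_monotonic_increasing:
        raise DataError(f"{path}: timestamps are not strictly increasing")
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate timestamps")
    return df


def read_accel(path: str | Path) -> pd.DataFrame:
    """Read an acceleration table (``timestamp,x,y,z``)."""
    return _read_table(path, ("timestamp", "x", "y", "z"))[["x", "y", "z"]]


def read_temp(path: str | Path) -> pd.DataFrame:
    """Read a temperature table (``timestamp,temp_c``)."""
    return _read_table(path, ("timestamp", "temp_c"))[["temp_c"]]


def read_recording(
    accel_path: str | Path,
    temp_path: str | Path | None = None,
    wrist: str = "left",
) -> RawRecording:
    """Read one wrist's acceleration (and optionally temperature) streams."""
    accel = read_accel(accel_path)
    temp = read_temp(temp_path) if temp_path is not None else None
    return RawRecording(wrist=wrist, accel=accel, temp=temp)


def write_accel(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index()
    out.columns = ["timestamp", "x", "y", "z"]
    out.to_csv(path, index=False, float_format="%.5f")


def write_temp(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index()
    out.columns = ["timestamp", "temp_c"]
    out.to_csv(path, index=False, float_format="%.3f")


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    """Read a behavior annotation table (``start,end,behavior,hand,severity``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    missing = [c for c in ("start", "end", "behavior") if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing columns {missing}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            AnnotationEvent(
                start=pd.Timestamp(row.start),
                end=pd.Timestamp(row.end),
                behavior=str(row.behavior),
                hand=str(getattr(row, "hand", "both")),
                severity=str(getattr(row, "severity", "none")),
            )
        )
    return events


def write_annotations(events: Iterable[AnnotationEvent], path: str | Path) -> None:
    rows = [
        {
            "start": e.start.isoformat(),
            "end": e.end.isoformat(),
            "behavior": e.behavior,
            "hand": e.hand,
            "severity": e.severity,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["start", "end", "behavior", "hand", "severity"]).to_csv(
        path, index=False
    )


def read_epochs(path: str | Path) -> pd.Series:
    """Read a reference epoch table (``epoch_start,state``) as a Series."""
    df = _read_table(path, ("epoch_start", "state"))
    return df["state"].astype(str)


def write_epochs(states: pd.Series, path: str | Path) -> None:
    out = states.rename("state").rename_axis("epoch_start").reset_index()
    out.to_csv(path, index=False)


def resample_accel(rec: RawRecording, target_rate: float = 20.0) -> RawRecording:
    """Down-sample the acceleration stream to ``target_rate`` Hz.

    Integer decimation ratios use an anti-aliased decimator; non-integer
    ratios fall back to linear interpolation onto a regular grid.
    Up-sampling is not supported.
    """
    rate = rec.accel_rate
    if target_rate > rate * (1 + 1e-9):
        raise ValueError(
            f"cannot upsample: target {target_rate} Hz exceeds source {rate:.6g} Hz"
        )
    if abs(rate - target_rate) / rate < 1e-9:
        return rec
    ratio = rate / target_rate
    t0 = rec.accel.index[0]
    if abs(ratio - round(ratio)) < 1e-6:
        q = int(round(ratio))
        # polyphase anti-aliased decimation; linear edge padding keeps the
        # boundary samples faithful
        data = signal.resample_poly(
            rec.accel[["x", "y", "z"]].to_numpy(dtype=float),
            up=1,
            down=q,
            axis=0,
            padtype="line",
        )
        index = t0 + pd.to_timedelta(np.arange(len(data)) / target_rate, unit="s")
    else:
        t = (rec.accel.index.view("int64") - t0.value) / 1e9
        new_t = np.arange(0.0, t[-1] + 0.5 / target_rate, 1.0 / target_rate)
        new_t = new_t[new_t <= t[-1] + 1e-9]
        data = np.column_stack(
            [np.interp(new_t, t, rec.accel[c].to_numpy(dtype=float)) for c in "xyz"]
        )
        index = t0 + pd.to_timedelta(new_t, unit="s")
    accel = pd.DataFrame(data, index=index, columns=["x", "y", "z"])
    accel.index.name = "timestamp"
    return RawRecording(
        wrist=rec.wrist,
        accel=accel,
        temp=rec.temp,
        accel_rate=target_rate,
        temp_rate=rec.temp_rate,
    )


def _noon_on_or_before(ts: pd.Timestamp) -> pd.Timestamp:
    noon = ts.normalize() + pd.Timedelta(hours=12)
    if ts < noon:
        noon -= pd.Timedelta(hours=24)
    return noon


def slice_days(rec: RawRecording, min_hours: float = 6.0) -> list[DaySegment]:
    """Slice a recording into noon-to-noon 24-h segments.

    Segments tile the recording span ``[first noon <= start, last noon >= end)``;
    segments with less than ``min_hours`` of recorded data are marked invalid.
    Recorded duration is measured as sample count / sampling rate, so gaps
    inside a slice do not count as recording time.
    """
    if len(rec.accel) == 0:
        raise DataError("cannot slice an empty recording")
    rate = rec.accel_rate
    first = _noon_on_or_before(rec.start)
    segments: list[DaySegment] = []
    day_start = first
    while day_start < rec.end or not segments:
        day_end = day_start + pd.Timedelta(hours=24)
        accel = rec.accel.loc[(rec.accel.index >= day_start) & (rec.accel.index < day_end)]
        temp = None
        if rec.temp is not None:
            temp = rec.temp.loc[(rec.temp.index >= day_start) & (rec.temp.index < day_end)]
        recorded_hours = len(accel) / rate / 3600.0 if rate > 0 else 0.0
        segments.append(
            DaySegment(
                day_start=day_start,
                accel=accel,
                temp=temp,
                recorded_hours=recorded_hours,
                valid=recorded_hours >= min_hours,
                wrist=rec.wrist,
                accel_rate=rate,
            )
        )
        day_start = day_end
    return segments


def segment_annotation(
    event: AnnotationEvent,
    window_s: float = 3.0,
    overlap_frac: float = 0.5,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Tile an annotation event into fixed-length training windows.

    Events shorter than ``window_s`` yield no windows.  Longer events are
    tiled stepping by ``window_s * (1 - overlap_frac)``; the final window is
    shifted so that it ends exactly at the event end.  Intervals are
    half-open ``[start, end)``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    dur = event.duration_s
    if dur < window_s - 1e-9:
        return []
    step = window_s * (1.0 - overlap_frac)
    n = int(np.floor((dur - window_s) / step + 1e-9)) + 1
    offsets = [i * step for i in range(n)]
    offsets[-1] = dur - window_s  # right-align the final window
    out = []
    for off in offsets:
        s = event.start + pd.Timedelta(seconds=off)
        out.append((s, s + pd.Timedelta(seconds=window_s)))
    return out
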