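"""Per-night digital endpoints of sleep quantity and scratch burden.

Sleep endpoints (minutes): total sleep opportunity (TSO), total sleep time
(TST) and percent time asleep (PTA = 100 * TST / TSO), plus exploratory
measures derived from the epoch series (sleep onset latency, wake after
sleep onset, number of wake bouts).  Scratch endpoints: total scratch
events (count of maximal runs of consecutive predicted-scratch windows) and
total scratch duration.

Across wrists, sleep endpoints are averaged and scratch endpoints summed.
Right-skewed scratch endpoints are compared on a log(x + 1) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .sleepwake import SLEEP
from .tso import TSOWindow

SLEEP_FIELDS = ("tso_minutes", "tst_minutes", "pta_percent", "nwb", "waso_minutes", "sol_minutes")
SCRATCH_FIELDS = ("scratch_events", "scratch_duration_minutes")


@dataclass
class NightEndpoints:
    """Digital measures for one night (one wrist, or a two-wrist aggregate)."""

    night_id: str
    wrist: str  # "left", "right" or "aggregate"
    tso_minutes: float = math.nan
    tst_minutes: float = math.nan
    pta_percent: float = math.nan
    scratch_events: float = math.nan
    scratch_duration_minutes: float = math.nan
    nwb: float = math.nan
    waso_minutes: float = math.nan
    sol_minutes: float = math.nan
    reason: str = ""

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def sleep_endpoints(epochs: pd.Series, tso: TSOWindow) -> tuple[float, float, float]:
    """(TSO minutes, TST minutes, PTA percent) from the epoch series.

    TST counts sleep epochs times the epoch length; epochs are assumed to
    tile the TSO window (trailing partial epoch excluded upstream).
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch series")
    epoch_min = _epoch_minutes(epochs)
    tso_min = tso.duration_min
    tst = float((epochs == SLEEP).sum()) * epoch_min
    pta = 100.0 * tst / tso_min
    return tso_min, tst, pta


def exploratory_sleep_endpoints(epochs: pd.Series) -> tuple[int, float, float]:
    """(NWB, WASO minutes, SOL minutes) from the epoch series.

    SOL is the time from TSO start to the first sleep epoch; WASO counts
    wake minutes after sleep onset; NWB counts maximal wake runs after
    onset.  With no sleep epoch at all the convention is SOL = full series
    duration, WASO = 0, NWB = 0.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch series")
    epoch_min = _epoch_minutes(epochs)
    asleep = (epochs == SLEEP).to_numpy()
    if not asleep.any():
        return 0, 0.0, len(epochs) * epoch_min
    onset = int(np.argmax(asleep))
    sol = onset * epoch_min
    after = asleep[onset:]
    waso = float((~after).sum()) * epoch_min
    wake_after = ~after
    padded = np.concatenate([[False], wake_after, [False]])
    nwb = int((np.diff(padded.astype(np.int8)) == 1).sum())
    return nwb, waso, sol


def scratch_endpoints(
    window_pred: pd.DataFrame | np.ndarray, window_s: float = 3.0
) -> tuple[int, float]:
    """(total scratch events, total scratch duration in minutes).

    A scratch bout is a maximal run of consecutive predicted-scratch
    windows among the non-overlapping 3-s windows of the night; events
    count bouts, duration sums their lengths.  Bouts are strictly
    contiguous: a single non-scratch window ends the bout.
    """
    if isinstance(window_pred, pd.DataFrame):
        is_scratch = (window_pred["pred"] == "scratch").to_numpy()
    else:
        arr = np.asarray(window_pred)
        is_scratch = arr == "scratch" if arr.dtype.kind in "OUS" else arr.astype(bool)
    padded = np.concatenate([[False], is_scratch, [False]])
    events = int((np.diff(padded.astype(np.int8)) == 1).sum())
    duration_min = float(is_scratch.sum()) * window_s / 60.0
    return events, duration_min


def aggregate_wrists(
    left: NightEndpoints | None, right: NightEndpoints | None
) -> NightEndpoints:
    """Two-wrist aggregate: sleep endpoints averaged, scratch endpoints summed.

    With one wrist missing the other wrist's values pass through and the
    aggregate is flagged (``reason = "single-wrist"``).
    """
    if left is None and right is None:
        raise ValueError("at least one wrist is required")
    if left is not None and right is not None and left.night_id != right.night_id:
        raise ValueError(
            f"mismatched nights: {left.night_id!r} vs {right.night_id!r}"
        )
    present = [e for e in (left, right) if e is not None]
    night_id = present[0].night_id
    agg = NightEndpoints(night_id=night_id, wrist="aggregate")
    if len(present) == 1:
        src = present[0]
        for name in SLEEP_FIELDS + SCRATCH_FIELDS:
            setattr(agg, name, getattr(src, name))
        agg.reason = "single-wrist"
        return agg
    for name in SLEEP_FIELDS:
        vals = [v for v in (getattr(left, name), getattr(right, name)) if not math.isnan(v)]
        setattr(agg, name, float(np.mean(vals)) if vals else math.nan)
    for name in SCRATCH_FIELDS:
        setattr(agg, name, getattr(left, name) + getattr(right, name))
    return agg


def log1p_transform(x: float) -> float:
    """Natural log of (x + 1); maps 0 to 0 and rejects negative input."""
    x = float(x)
    if x < 0:
        raise ValueError("log1p endpoint transform requires x >= 0")
    return math.log1p(x)


def _epoch_minutes(epochs: pd.Series) -> float:
    if len(epochs) > 1 and isinstance(epochs.index, pd.DatetimeIndex):
        return (epochs.index[1] - epochs.index[0]).total_seconds() / 60.0
    return 1.0
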