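"""Sleep/wake scoring of 1-min epochs inside the TSO window.

Scoring follows the classic actigraphy recipe: a per-epoch activity level is
fed to a weighted moving sum over neighbouring epochs (the Cole-Kripke
1-min heuristic), an epoch is scored *sleep* when the sum falls below 1, and
Webster's rescoring rules are then applied to improve wake specificity.

Devices here expose raw acceleration rather than proprietary activity
counts, so the activity level is the open activity index: the square root of
the mean over the three axes of the per-axis signal variance in the epoch
(optionally noise-floor corrected).  A ``scale`` calibration constant maps
index units onto the count scale the weighted sum expects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tso import TSOWindow

SLEEP = "sleep"
WAKE = "wake"

#: Published 1-min Cole-Kripke weights for epochs t-4 .. t+2.
COLE_KRIPKE_WEIGHTS: tuple[float, ...] = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)
COLE_KRIPKE_OFFSETS: tuple[int, ...] = (-4, -3, -2, -1, 0, 1, 2)

#: Calibration from activity-index units (g) to the count scale of the
#: weighted sum; chosen so quiet sleep scores far below the sleep threshold
#: of 1 and overt wake movement far above it (see docs/methods.md).
DEFAULT_SCALE = 0.05


def activity_index(window: np.ndarray | pd.DataFrame, noise_var: float = 0.0) -> float:
    """Activity index of one tri-axial acceleration window.

    ``sqrt(max(0, mean_axes(var_axis) - noise_var))`` -- zero for a constant
    window, approximately the per-axis noise SD for i.i.d. noise.
    """
    arr = np.asarray(window, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("window must be an (n, 3) array")
    if arr.shape[0] < 2:
        return 0.0
    v = arr.var(axis=0, ddof=1).mean() - noise_var
    if v < 1e-12:  # constant windows carry float round-off
        return 0.0
    return float(np.sqrt(v))


def activity_series(
    accel: pd.DataFrame,
    tso: TSOWindow,
    rate: float,
    epoch_s: int = 60,
    noise_var: float = 0.0,
) -> pd.Series:
    """Per-epoch activity index over the TSO window.

    Epochs are aligned to the TSO start; a trailing partial epoch is dropped.
    """
    sel = accel.loc[(accel.index >= tso.start) & (accel.index < tso.end)]
    n_epochs = int((tso.end - tso.start).total_seconds() // epoch_s)
    if n_epochs == 0:
        raise ValueError("TSO window shorter than one epoch")
    starts = tso.start + pd.to_timedelta(np.arange(n_epochs) * epoch_s, unit="s")
    arr = sel[["x", "y", "z"]].to_numpy(dtype=float)
    offsets = ((sel.index - tso.start).total_seconds() // epoch_s).astype(int)
    vals = np.zeros(n_epochs)
    for i in range(n_epochs):
        w = arr[offsets == i]
        vals[i] = activity_index(w, noise_var) if len(w) >= 2 else 0.0
    out = pd.Series(vals, index=starts, name="activity")
    out.index.name = "epoch_start"
    return out


class ColeKripkeScorer(BaseEstimator):
    """Score 1-min epochs sleep/wake from an activity series.

    The epoch score is ``D_t = scale * sum_k w_k * A_{t+k}`` over offsets
    t-4..t+2 (missing neighbours treated as zero activity); the epoch is
    scored sleep iff ``D_t < 1``.

    Parameters
    ----------
    weights : 7 weights for epoch offsets -4..+2.
    scale : calibration constant applied to the weighted sum.
    """

    def __init__(
        self,
        weights: Sequence[float] = COLE_KRIPKE_WEIGHTS,
        scale: float = DEFAULT_SCALE,
    ):
        self.weights = weights
        self.scale = scale

    def score(self, activity: pd.Series | np.ndarray) -> np.ndarray:
        """The weighted-sum score D_t for each epoch."""
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(COLE_KRIPKE_OFFSETS),):
            raise ValueError(
                f"weights must have length {len(COLE_KRIPKE_OFFSETS)}, got {w.shape}"
            )
        a = np.asarray(activity, dtype=float)
        n = len(a)
        d = np.zeros(n)
        for wk, off in zip(w, COLE_KRIPKE_OFFSETS):
            lo, hi = max(0, -off), min(n, n - off)
            d[lo:hi] += wk * a[lo + off : hi + off]
        return self.scale * d

    def predict(self, activity: pd.Series | np.ndarray) -> np.ndarray:
        """State per epoch: ``"sleep"`` iff D_t < 1 else ``"wake"``."""
        d = self.score(activity)
        return np.where(d < 1.0, SLEEP, WAKE)


def sleep_wake_epoch(
    activity: pd.Series,
    weights: Sequence[float] = COLE_KRIPKE_WEIGHTS,
    scale: float = DEFAULT_SCALE,
) -> pd.Series:
    """Functional wrapper around :class:`ColeKripkeScorer`."""
    states = ColeKripkeScorer(weights=weights, scale=scale).predict(activity)
    return pd.Series(states, index=activity.index, name="state")


# Webster's five rescoring rules, expressed as (min preceding wake run,
# number of following sleep epochs rescored) for the first three, and
# (max sleep island length, min flanking wake run) for the last two.
_AFTER_RULES = ((15, 4), (10, 3), (4, 1))
_ISLAND_RULES = ((6, 10), (10, 20))


def webster_rescore(
    states: Sequence[str] | np.ndarray | pd.Series,
    rules: Sequence[bool] = (True, True, True, True, True),
) -> np.ndarray | pd.Series:
    """Apply Webster's rescoring rules to a 1-min sleep/wake sequence.

    Rules (each individually switchable, applied in order):

    1. after >= 4 min scored wake, the next 1 min of sleep is rescored wake
    2. after >= 10 min scored wake, the next 3 min of sleep are rescored
    3. after >= 15 min scored wake, the next 4 min of sleep are rescored
    4. <= 6 min of sleep surrounded by >= 10 min wake on both sides is rescored
    5. <= 10 min of sleep surrounded by >= 20 min wake on both sides is rescored

    Only sleep -> wake changes are ever made, so total sleep time never
    increases.  Rescored epochs count as wake for subsequent rules.
    """
    index = states.index if isinstance(states, pd.Series) else None
    arr = np.asarray(states, dtype=object)
    sleep = arr == SLEEP
    if len(rules) != 5:
        raise ValueError("rules must be a 5-element on/off sequence")

    out = sleep.copy()
    n = len(out)

    # rules 1-3: wake runs trigger rescoring of the sleep epochs that follow;
    # checked in decreasing order of wake-run requirement so the strongest
    # applicable rule wins
    enabled_after = [
        (need, count)
        for (need, count), on in zip(_AFTER_RULES, (rules[2], rules[1], rules[0]))
        if on
    ]
    wake_run = 0
    i = 0
    while i < n:
        if not out[i]:
            wake_run += 1
            i += 1
            continue
        run_len = 1
        while i + run_len < n and out[i + run_len]:
            run_len += 1
        count = 0
        for need, cnt in enabled_after:
            if wake_run >= need:
                count = cnt
                break
        k = min(count, run_len)
        out[i : i + k] = False
        if k < run_len:
            wake_run = 0  # genuine sleep survives; wake run is broken
        else:
            wake_run += run_len  # whole run rescored; wake run extends
        i += run_len

    # rules 4-5: short sleep islands flanked by long wake runs
    for (max_len, need), on in zip(_ISLAND_RULES, (rules[3], rules[4])):
        if not on:
            continue
        for s, e in _sleep_runs(out):
            if e - s > max_len:
                continue
            before = _wake_run_ending_at(out, s)
            after_run = _wake_run_starting_at(out, e)
            if before >= need and after_run >= need:
                out[s:e] = False

    result = np.where(out, SLEEP, WAKE)
    if index is not None:
        return pd.Series(result, index=index, name="state")
    return result


def _sleep_runs(sleep: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], sleep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _wake_run_ending_at(sleep: np.ndarray, idx: int) -> int:
    n = 0
    i = idx - 1
    while i >= 0 and not sleep[i]:
        n += 1
        i -= 1
    return n


def _wake_run_starting_at(sleep: np.ndarray, idx: int) -> int:
    n = 0
    i = idx
    while i < len(sleep) and not sleep[i]:
        n += 1
        i += 1
    return n


def to_30s_epochs(states: pd.Series) -> pd.Series:
    """Duplicate 1-min states into 30-s epochs for reference comparison."""
    starts = []
    vals = []
    for ts, st in states.items():
        starts.extend([ts, ts + pd.Timedelta(seconds=30)])
        vals.extend([st, st])
    out = pd.Series(vals, index=pd.DatetimeIndex(starts), name="state")
    out.index.name = "epoch_start"
    return out
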