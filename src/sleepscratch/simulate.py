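"""Synthetic overnight wrist recordings with ground-truth labels.

The simulator emulates the statistical structure the pipeline assumes, not
limb biomechanics: tri-axial acceleration is a slowly re-orienting gravity
vector plus movement noise whose magnitude tracks the behavioral state,
with scratch bouts inserted as fast (2.5-5 Hz), amplitude-modulated,
impulsive oscillations and restless bouts as slower (0.5-1.5 Hz), smooth
repositioning movements.  Near-body temperature relaxes exponentially
toward a wear- or non-wear-dependent target.  Every night returns the
scripted truth: the intended sleep window, 1-min sleep/wake states, bout
annotations and wear intervals, written in the same CSV dialects the rest
of the package consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationEvent,
    RawRecording,
    write_accel,
    write_annotations,
    write_epochs,
    write_temp,
)
from .tso import TSOWindow

HAND_PROBS = {"left": 0.4, "right": 0.4, "both": 0.2}
SEVERITY_AMP = {"mild": 0.6, "moderate": 1.0, "severe": 1.5}
SEVERITY_PROBS = {"mild": 0.3, "moderate": 0.5, "severe": 0.2}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a realistic overnight wear session: recording from
    18:00 to 10:00 the next day, lights out around 23:00, rise around
    07:00, about six scratch and six restless bouts per hour of night with
    ~10 s median duration, quiet sleep at the accelerometer noise floor and
    overt movement during wake.
    """

    seed: int = 0
    n_subjects: int = 10
    start_date: str = "2024-03-01"
    rec_start: str = "18:00"
    rec_hours: float = 16.0
    night_start: str = "23:00"
    night_end: str = "07:00"
    schedule_jitter_min: float = 20.0
    fs: float = 20.0
    temp_period_s: float = 1.0 / 0.334

    # movement noise (g)
    wake_sd: float = 0.10
    inbed_wake_sd: float = 0.04
    sleep_sd: float = 0.005
    wake_reorient_s: float = 60.0

    # night structure
    night_wake_bouts: int = 2
    night_wake_dur_min: float = 6.0

    # scratch / restless bouts
    scratch_bout_rate: float = 6.0  # per hour of night
    restless_bout_rate: float = 6.0
    bout_dur_log_mu: float = math.log(10.0)
    bout_dur_log_sigma: float = 0.5
    scratch_band: tuple[float, float] = (2.5, 5.0)
    restless_band: tuple[float, float] = (0.5, 1.5)
    scratch_amp: float = 0.35
    restless_amp: float = 0.30
    difficulty: float = 1.0

    # temperature (Celsius)
    wear_temp: float = 32.0
    nonwear_temp: float = 22.0
    temp_tau_min: float = 5.0
    temp_noise: float = 0.1
    #: off-body episodes as (offset hours from recording start, duration min)
    nonwear_episodes: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for band in (self.scratch_band, self.restless_band):
            if not (0 < band[0] < band[1]):
                raise ValueError("frequency bands must be positive and ordered")
        if self.scratch_bout_rate < 0 or self.restless_bout_rate < 0:
            raise ValueError("bout rates must be non-negative")
        if self.wear_temp == self.nonwear_temp:
            raise ValueError("wear and non-wear temperatures must differ")


@dataclass
class SimulatedNight:
    """One subject-night: both wrists plus the scripted ground truth."""

    subject_id: int
    left: RawRecording
    right: RawRecording
    tso: TSOWindow
    events: list[AnnotationEvent]
    sleep_epochs: pd.Series  # 1-min truth states over the scripted night
    wear_intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
    wake_bouts: list[tuple[pd.Timestamp, pd.Timestamp]]

    def truth_states(self, epoch_starts, epoch_s: float = 60.0) -> np.ndarray:
        """Scripted sleep/wake state at each epoch (by epoch midpoint).

        Epochs whose midpoint falls outside the scripted night are labeled
        ``"none"``; inside the night, epochs overlapping an in-bed wake bout
        at their midpoint are ``"wake"``, the rest ``"sleep"``.
        """
        mids = pd.DatetimeIndex(epoch_starts) + pd.Timedelta(seconds=epoch_s / 2)
        out = np.full(len(mids), "none", dtype=object)
        inside = (mids >= self.tso.start) & (mids < self.tso.end)
        out[np.asarray(inside)] = "sleep"
        for ws, we in self.wake_bouts:
            hit = inside & (mids >= ws) & (mids < we)
            out[np.asarray(hit)] = "wake"
        return out

    def true_window_labels(
        self, window_starts, wrist: str, window_s: float = 3.0, min_overlap: float = 0.5
    ) -> np.ndarray:
        """Scripted behavior label per 3-s window for one wrist.

        A window is labeled ``scratch`` (or ``restless``) when at least
        ``min_overlap`` of it overlaps an event of that behavior annotated
        for this wrist (hand == wrist or "both"); otherwise ``"none"``.
        Scratch takes precedence where both behaviors overlap.
        """
        starts = pd.DatetimeIndex(window_starts)
        ends = starts + pd.Timedelta(seconds=window_s)
        out = np.full(len(starts), "none", dtype=object)
        for behavior in ("restless", "scratch"):  # scratch last: wins ties
            for ev in self.events:
                if ev.behavior != behavior or ev.hand not in (wrist, "both"):
                    continue
                ov = (np.minimum(ends.values, np.datetime64(ev.end))
                      - np.maximum(starts.values, np.datetime64(ev.start)))
                frac = ov / np.timedelta64(1, "s") / window_s
                out[frac >= min_overlap] = behavior
        return out


def _clock_ts(date: str, clock: str, day_offset: int = 0) -> pd.Timestamp:
    return pd.Timestamp(f"{date} {clock}") + pd.Timedelta(days=day_offset)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _bout_signal(
    behavior: str,
    n: int,
    fs: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    freq_offset: float,
    amp_factor: float,
) -> np.ndarray:
    """(n, 3) acceleration deviation for one scratch or restless bout."""
    t = np.arange(n) / fs
    if behavior == "scratch":
        lo, hi = cfg.scratch_band
        f0 = np.clip(rng.uniform(lo, hi) + freq_offset, 0.3, fs / 2 * 0.9)
        amp = cfg.scratch_amp * amp_factor
        env = np.ones(n)
        am = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.3, 0.9) * t + rng.uniform(0, 2 * np.pi))
        env *= am
        direction = _random_unit(rng)
        phase = rng.uniform(0, 2 * np.pi)
        sig = np.outer(amp * env * np.sin(2 * np.pi * f0 * t + phase), direction)
        # impulsive jerk: brief spikes at roughly the oscillation rate
        n_spikes = rng.poisson(max(f0 * n / fs, 1.0))
        for _ in range(n_spikes):
            i = rng.integers(0, max(n - 2, 1))
            sig[i : i + 2] += _random_unit(rng) * amp * rng.uniform(0.5, 1.0)
        sig += rng.normal(0, 0.03 * cfg.difficulty, size=(n, 3))
    else:
        lo, hi = cfg.restless_band
        f0 = np.clip(rng.uniform(lo, hi) + 0.3 * freq_offset, 0.1, fs / 2 * 0.9)
        amp = cfg.restless_amp * amp_factor
        # smooth repositioning keeps moving throughout the bout: Hann shape
        # with an amplitude floor plus a small broadband tremor component
        env = 0.3 + 0.7 * (np.hanning(n) if n > 2 else np.ones(n))
        direction = _random_unit(rng)
        phase = rng.uniform(0, 2 * np.pi)
        sig = np.outer(amp * env * np.sin(2 * np.pi * f0 * t + phase), direction)
        sig += rng.normal(0, 0.04, size=(n, 3))
    # ramp the edges so bouts start and end gently
    edge = max(2, int(0.05 * n))
    ramp = np.ones(n)
    ramp[:edge] = np.linspace(0, 1, edge)
    ramp[-edge:] = np.linspace(1, 0, edge)
    return sig * ramp[:, None]


def _schedule(cfg: SimConfig, subject_id: int) -> dict:
    """Subject-level night schedule and bout script, shared by both wrists."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2**31), 1000 + subject_id])
    )
    rec_start = _clock_ts(cfg.start_date, cfg.rec_start)
    rec_end = rec_start + pd.Timedelta(hours=cfg.rec_hours)
    jitter = pd.Timedelta(minutes=float(rng.uniform(-1, 1) * cfg.schedule_jitter_min))
    night_start = _clock_ts(cfg.start_date, cfg.night_start) + jitter
    if night_start.time() < rec_start.time() and night_start < rec_start:
        night_start += pd.Timedelta(days=1)
    jitter2 = pd.Timedelta(minutes=float(rng.uniform(-1, 1) * cfg.schedule_jitter_min))
    night_end = _clock_ts(cfg.start_date, cfg.night_end, day_offset=1) + jitter2
    night_end = min(night_end, rec_end - pd.Timedelta(minutes=30))
    night_hours = (night_end - night_start).total_seconds() / 3600.0
    if night_hours <= 0:
        raise ValueError("infeasible schedule: night has non-positive duration")

    # brief in-bed wake bouts (WASO)
    wake_bouts = []
    for _ in range(cfg.night_wake_bouts):
        dur = pd.Timedelta(minutes=float(rng.uniform(0.5, 1.5) * cfg.night_wake_dur_min))
        start = night_start + pd.Timedelta(
            seconds=float(rng.uniform(0.1, 0.85) * (night_end - night_start).total_seconds())
        )
        wake_bouts.append((start, min(start + dur, night_end)))
    wake_bouts.sort()

    # scratch / restless bout script
    freq_offset = float(rng.normal(0, 0.25 * cfg.difficulty))
    n_scratch = rng.poisson(cfg.scratch_bout_rate * night_hours)
    n_restless = rng.poisson(cfg.restless_bout_rate * night_hours)
    behaviors = ["scratch"] * n_scratch + ["restless"] * n_restless
    events: list[AnnotationEvent] = []
    night_s = (night_end - night_start).total_seconds()
    total_bout_s = 0.0
    proposals = []
    for beh in behaviors:
        dur = float(np.clip(rng.lognormal(cfg.bout_dur_log_mu, cfg.bout_dur_log_sigma), 3.0, 120.0))
        start_s = float(rng.uniform(0, max(night_s - dur, 1.0)))
        proposals.append((start_s, dur, beh))
        total_bout_s += dur
    if total_bout_s > 0.5 * night_s:
        raise ValueError("infeasible schedule: bouts would cover most of the night")
    proposals.sort()
    last_end = -math.inf
    for start_s, dur, beh in proposals:
        if start_s < last_end + 2.0:  # keep bouts separated by >= 2 s
            continue
        hand = rng.choice(list(HAND_PROBS), p=list(HAND_PROBS.values()))
        severity = rng.choice(list(SEVERITY_PROBS), p=list(SEVERITY_PROBS.values()))
        start = night_start + pd.Timedelta(seconds=start_s)
        events.append(
            AnnotationEvent(
                start=start,
                end=start + pd.Timedelta(seconds=dur),
                behavior=beh,
                hand=str(hand),
                severity=str(severity) if beh == "scratch" else "none",
            )
        )
        last_end = start_s + dur

    return {
        "rec_start": rec_start,
        "rec_end": rec_end,
        "night_start": night_start,
        "night_end": night_end,
        "wake_bouts": wake_bouts,
        "events": events,
        "freq_offset": freq_offset,
        "sleep_positions": [  # orientation keyframes used while in bed
            _random_unit(rng) for _ in range(len(wake_bouts) + 1)
        ],
    }


def _wrist_accel(
    cfg: SimConfig, sched: dict, wrist: str, rng: np.random.Generator
) -> pd.DataFrame:
    fs = cfg.fs
    rec_start, rec_end = sched["rec_start"], sched["rec_end"]
    n = int(round((rec_end - rec_start).total_seconds() * fs))
    t_s = np.arange(n) / fs
    index = rec_start + pd.to_timedelta(t_s, unit="s")

    night_start_s = (sched["night_start"] - rec_start).total_seconds()
    night_end_s = (sched["night_end"] - rec_start).total_seconds()
    in_night = (t_s >= night_start_s) & (t_s < night_end_s)

    # orientation keyframes: frequent re-orientation while awake, stable
    # positions (changing only at wake bouts) while in bed
    key_t: list[float] = []
    key_o: list[np.ndarray] = []
    step = cfg.wake_reorient_s
    for t0 in np.arange(0.0, night_start_s, step):
        key_t.append(t0)
        key_o.append(_random_unit(rng))
    positions = sched["sleep_positions"]
    key_t.append(night_start_s)
    key_o.append(positions[0])
    for i, (ws, we) in enumerate(sched["wake_bouts"]):
        ts0 = (ws - rec_start).total_seconds()
        key_t.extend([ts0, ts0 + 10.0])
        key_o.extend([positions[i], positions[i + 1]])
    key_t.append(night_end_s)
    key_o.append(positions[len(sched["wake_bouts"])])
    for t0 in np.arange(night_end_s + step, n / fs, step):
        key_t.append(t0)
        key_o.append(_random_unit(rng))
    key_t.append(n / fs)
    key_o.append(_random_unit(rng))
    key_t_arr = np.asarray(key_t)
    key_o_arr = np.asarray(key_o)
    order = np.argsort(key_t_arr, kind="stable")
    key_t_arr, key_o_arr = key_t_arr[order], key_o_arr[order]
    gravity = np.column_stack(
        [np.interp(t_s, key_t_arr, key_o_arr[:, i]) for i in range(3)]
    )
    gravity /= np.maximum(np.linalg.norm(gravity, axis=1, keepdims=True), 1e-9)

    # state-dependent movement noise
    sd = np.full(n, cfg.wake_sd)
    sd[in_night] = cfg.sleep_sd
    for ws, we in sched["wake_bouts"]:
        s0 = int((ws - rec_start).total_seconds() * fs)
        s1 = int((we - rec_start).total_seconds() * fs)
        sd[s0:s1] = cfg.inbed_wake_sd
    accel = gravity + rng.normal(size=(n, 3)) * sd[:, None]

    # in-bed wake is restless-style repositioning, not white noise
    for ws, we in sched["wake_bouts"]:
        s0 = int((ws - rec_start).total_seconds() * fs)
        s1 = min(int((we - rec_start).total_seconds() * fs), n)
        if s1 > s0:
            accel[s0:s1] += _bout_signal(
                "restless", s1 - s0, fs, cfg, rng, sched["freq_offset"], 0.5
            )

    # scratch / restless bouts on the wrist(s) the annotation names
    for ev in sched["events"]:
        if ev.hand not in (wrist, "both"):
            continue
        s0 = int((ev.start - rec_start).total_seconds() * fs)
        s1 = min(int((ev.end - rec_start).total_seconds() * fs), n)
        if s1 <= s0:
            continue
        amp_factor = SEVERITY_AMP.get(ev.severity, 1.0)
        accel[s0:s1] += _bout_signal(
            ev.behavior, s1 - s0, fs, cfg, rng, sched["freq_offset"], amp_factor
        )

    df = pd.DataFrame(accel, index=index, columns=["x", "y", "z"])
    df.index.name = "timestamp"
    return df


def _wrist_temp(cfg: SimConfig, sched: dict, rng: np.random.Generator) -> pd.DataFrame:
    rec_start, rec_end = sched["rec_start"], sched["rec_end"]
    dt = cfg.temp_period_s
    n = int((rec_end - rec_start).total_seconds() / dt)
    t_s = np.arange(n) * dt
    worn = np.ones(n, dtype=bool)
    for off_h, dur_min in cfg.nonwear_episodes:
        s0 = off_h * 3600.0
        worn[(t_s >= s0) & (t_s < s0 + dur_min * 60.0)] = False
    target = np.where(worn, cfg.wear_temp, cfg.nonwear_temp)
    tau = cfg.temp_tau_min * 60.0
    alpha = 1.0 - math.exp(-dt / tau)
    temp = np.empty(n)
    cur = float(target[0])
    for i in range(n):
        cur += (target[i] - cur) * alpha
        temp[i] = cur
    temp += rng.normal(0, cfg.temp_noise, size=n)
    index = rec_start + pd.to_timedelta(t_s, unit="s")
    df = pd.DataFrame({"temp_c": temp}, index=index)
    df.index.name = "timestamp"
    return df


def _truth_sleep_epochs(sched: dict) -> pd.Series:
    start, end = sched["night_start"], sched["night_end"]
    n_min = int((end - start).total_seconds() // 60)
    starts = start + pd.to_timedelta(np.arange(n_min), unit="min")
    states = np.full(n_min, "sleep", dtype=object)
    for ws, we in sched["wake_bouts"]:
        overlap = (starts < we) & (starts + pd.Timedelta(minutes=1) > ws)
        states[np.asarray(overlap)] = "wake"
    out = pd.Series(states, index=pd.DatetimeIndex(starts), name="state")
    out.index.name = "epoch_start"
    return out


def simulate_recording(cfg: SimConfig, subject_id: int = 0) -> SimulatedNight:
    """Simulate one subject-night (both wrists) with ground truth.

    Deterministic: the same config and subject id always produce
    bit-identical output.
    """
    sched = _schedule(cfg, subject_id)
    recs = {}
    for widx, wrist in enumerate(("left", "right")):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) % (2**31), 1000 + subject_id, widx])
        )
        accel = _wrist_accel(cfg, sched, wrist, rng)
        temp = _wrist_temp(cfg, sched, rng)
        recs[wrist] = RawRecording(
            wrist=wrist, accel=accel, temp=temp, accel_rate=cfg.fs,
            temp_rate=1.0 / cfg.temp_period_s,
        )
    wear_intervals = [(sched["rec_start"], sched["rec_end"])]
    if cfg.nonwear_episodes:
        wear_intervals = []  # callers consult nonwear_episodes directly
    return SimulatedNight(
        subject_id=subject_id,
        left=recs["left"],
        right=recs["right"],
        tso=TSOWindow(start=sched["night_start"], end=sched["night_end"]),
        events=sched["events"],
        sleep_epochs=_truth_sleep_epochs(sched),
        wear_intervals=wear_intervals,
        wake_bouts=list(sched["wake_bouts"]),
    )


def simulate_cohort(
    cfg: SimConfig, n: int | None = None, out_dir: str | Path | None = None
) -> list[SimulatedNight]:
    """Simulate ``n`` subjects; optionally write the CSV dataset layout.

    Layout per subject: ``subject_XX/{left,right}_{accel,temp}.csv``,
    ``annotations.csv``, ``truth_tso.csv`` and ``truth_sleep_epochs.csv``.
    """
    n = cfg.n_subjects if n is None else n
    if n < 1:
        raise ValueError("need at least one subject")
    nights = [simulate_recording(cfg, subject_id=i) for i in range(n)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        for night in nights:
            sub = out_dir / f"subject_{night.subject_id:02d}"
            sub.mkdir(parents=True, exist_ok=True)
            write_accel(night.left.accel, sub / "left_accel.csv")
            write_temp(night.left.temp, sub / "left_temp.csv")
            write_accel(night.right.accel, sub / "right_accel.csv")
            write_temp(night.right.temp, sub / "right_temp.csv")
            write_annotations(night.events, sub / "annotations.csv")
            pd.DataFrame(
                [{"tso_start": night.tso.start.isoformat(), "tso_end": night.tso.end.isoformat()}]
            ).to_csv(sub / "truth_tso.csv", index=False)
            write_epochs(night.sleep_epochs, sub / "truth_sleep_epochs.csv")
    return nights


def simulate_labeled_windows(
    cfg: SimConfig,
    n_subjects: int | None = None,
    windows_per_subject: int = 120,
    window_s: float = 3.0,
    seed_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labeled raw 3-s windows straight from the bout generators.

    A fast path for classifier experiments: per subject, equal numbers of
    scratch and restless windows are generated (gravity at a random stable
    orientation plus the bout oscillation), skipping the full-night
    embedding.  Returns ``(raw windows (n, samples, 3), labels, subjects)``.
    """
    n_subjects = cfg.n_subjects if n_subjects is None else n_subjects
    ns = int(round(window_s * cfg.fs))
    X, y, subj = [], [], []
    for sid in range(n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) % (2**31), 5000 + seed_offset, sid])
        )
        freq_offset = float(rng.normal(0, 0.25 * cfg.difficulty))
        for k in range(windows_per_subject):
            behavior = "scratch" if k % 2 == 0 else "restless"
            gravity = _random_unit(rng)
            severity = rng.choice(list(SEVERITY_PROBS), p=list(SEVERITY_PROBS.values()))
            amp_factor = SEVERITY_AMP[str(severity)] if behavior == "scratch" else 1.0
            win = gravity[None, :] + rng.normal(0, cfg.sleep_sd, size=(ns, 3))
            win += _bout_signal(behavior, ns, cfg.fs, cfg, rng, freq_offset, amp_factor)
            X.append(win)
            y.append(behavior)
            subj.append(sid)
    return np.asarray(X), np.asarray(y), np.asarray(subj)
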