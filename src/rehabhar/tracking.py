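"""Turning window predictions into daily exercise-time logs.

The recognizer emits one class per sliding window; the tracker smooths
that sequence (sliding majority vote), suppresses isolated flickers
shorter than a minimum bout, and credits each class with
``window count x stride`` seconds — the stride, not the window length,
so overlapping windows tile time without double counting.  Daily logs
feed the two app views: the patient's last-3-days summary and the
therapist's last-month cohort table.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .classes import EXERCISES, ExerciseClass

MINUTES_PER_DAY = 24 * 60


@dataclasses.dataclass
class PredictionStream:
    """Ordered window predictions for one recording.

    start_times_s must advance by exactly ``stride_s`` per window.
    """

    start_times_s: np.ndarray
    labels: list[ExerciseClass]
    stride_s: float
    window_s: float = 3.0
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if self.stride_s <= 0:
            raise ValueError("stride must be positive")
        if len(self.labels) != self.start_times_s.size:
            raise ValueError("labels and start times differ in length")
        diffs = np.diff(self.start_times_s)
        if diffs.size and not np.allclose(diffs, self.stride_s, atol=1e-6):
            raise ValueError("start times must increase uniformly by the stride")


@dataclasses.dataclass
class ExerciseLog:
    """Per-day, per-exercise minutes for one patient (rest excluded)."""

    subject_id: str
    date: datetime.date
    minutes: dict[ExerciseClass, float]

    def __post_init__(self) -> None:
        self.minutes = {
            c: float(self.minutes.get(c, 0.0)) for c in EXERCISES
        }
        if any(v < 0 for v in self.minutes.values()):
            raise ValueError("minutes must be non-negative")
        if self.total_minutes > MINUTES_PER_DAY:
            raise ValueError("daily total exceeds 24 hours")

    @property
    def total_minutes(self) -> float:
        return float(sum(self.minutes.values()))


def smooth_labels(
    labels: Sequence[ExerciseClass], smoothing: int = 5
) -> list[ExerciseClass]:
    """Sliding majority vote over ``smoothing`` windows (centered,
    truncated at the ends); ties go to NO_EXERCISE."""
    if smoothing < 1:
        raise ValueError("smoothing length must be >= 1")
    if smoothing == 1:
        return list(labels)
    arr = np.array([int(c) for c in labels])
    half = smoothing // 2
    out = []
    for i in range(arr.size):
        seg = arr[max(0, i - half) : i + half + 1]
        counts = np.bincount(seg, minlength=len(ExerciseClass))
        leaders = np.flatnonzero(counts == counts.max())
        out.append(ExerciseClass(int(leaders[0])))  # NO_EXERCISE is index 0
    return out


def enforce_min_bout(
    labels: Sequence[ExerciseClass], min_bout: int = 2
) -> list[ExerciseClass]:
    """Relabel maximal exercise runs shorter than ``min_bout`` windows
    as NO_EXERCISE."""
    if min_bout < 1:
        raise ValueError("min bout must be >= 1")
    arr = np.array([int(c) for c in labels])
    out = arr.copy()
    if arr.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [arr.size]])
    for s, e in zip(starts, ends):
        if arr[s] != int(ExerciseClass.NO_EXERCISE) and (e - s) < min_bout:
            out[s:e] = int(ExerciseClass.NO_EXERCISE)
    return [ExerciseClass(int(v)) for v in out]


def predictions_to_log(
    stream: PredictionStream,
    subject_id: str,
    date: datetime.date,
    smoothing: int = 5,
    min_bout: int = 2,
) -> ExerciseLog:
    """Credit exercise time from a prediction stream.

    Time per class = (windows labeled with it after smoothing and
    bout filtering) x stride seconds.
    """
    labels = smooth_labels(stream.labels, smoothing=smoothing)
    labels = enforce_min_bout(labels, min_bout=min_bout)
    arr = np.array([int(c) for c in labels])
    minutes = {
        c: float(np.sum(arr == int(c))) * stream.stride_s / 60.0 for c in EXERCISES
    }
    return ExerciseLog(subject_id=subject_id, date=date, minutes=minutes)


def merge_logs(logs: Sequence[ExerciseLog]) -> list[ExerciseLog]:
    """Sum logs that share (subject, date) into one log per day."""
    acc: dict[tuple[str, datetime.date], dict[ExerciseClass, float]] = {}
    for log in logs:
        key = (log.subject_id, log.date)
        slot = acc.setdefault(key, {c: 0.0 for c in EXERCISES})
        for c in EXERCISES:
            slot[c] += log.minutes[c]
    return [
        ExerciseLog(subject_id=s, date=d, minutes=m) for (s, d), m in sorted(acc.items())
    ]


def summarize_recent(
    logs: Sequence[ExerciseLog],
    n_days: int = 3,
    today: datetime.date | None = None,
) -> pd.DataFrame:
    """Patient view: per-exercise and total minutes for the last
    ``n_days`` calendar dates ending today, zero-filled where no log
    exists.  All logs must belong to one subject."""
    subjects = {log.subject_id for log in logs}
    if len(subjects) > 1:
        raise ValueError(f"summarize_recent expects one subject, got {sorted(subjects)}")
    if today is None:
        today = datetime.date.today()
    merged = {log.date: log for log in merge_logs(list(logs))}
    dates = [today - datetime.timedelta(days=i) for i in range(n_days - 1, -1, -1)]
    rows = []
    for d in dates:
        log = merged.get(d)
        row = {c.name: (log.minutes[c] if log else 0.0) for c in EXERCISES}
        row["total"] = sum(row.values())
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(dates, name="date"))


def summarize_cohort(
    logs: Sequence[ExerciseLog],
    window_days: int = 30,
    today: datetime.date | None = None,
) -> pd.DataFrame:
    """Therapist view: one row per subject over the trailing window —
    active days, mean minutes/day (averaged over the whole window, not
    just active days), and per-exercise totals."""
    if today is None:
        today = datetime.date.today()
    start = today - datetime.timedelta(days=window_days - 1)
    rows = {}
    merged = merge_logs([log for log in logs if start <= log.date <= today])
    for log in merged:
        row = rows.setdefault(
            log.subject_id,
            {"active_days": 0, "mean_min_per_day": 0.0}
            | {c.name: 0.0 for c in EXERCISES},
        )
        if log.total_minutes > 0:
            row["active_days"] += 1
        for c in EXERCISES:
            row[c.name] += log.minutes[c]
    for row in rows.values():
        row["mean_min_per_day"] = sum(row[c.name] for c in EXERCISES) / window_days
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df.sort_index()
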