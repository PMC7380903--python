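"""Labeled IMU session container, CSV I/O and sliding-window segmentation.

A session is one subject's time-ordered 6-axis stream (3-axis
accelerometer in m/s², 3-axis gyroscope in rad/s) at a nominal 10 Hz,
with a per-sample exercise label.  The classifier consumes fixed-length
windows of 3 s (30 samples) cut with a configurable stride.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classes import CHANNELS, ExerciseClass

DEFAULT_RATE_HZ = 10.0
CSV_HEADER = ("t",) + CHANNELS + ("label",)


@dataclasses.dataclass
class LabeledSession:
    """One subject's labeled 6-axis IMU recording.

    Parameters
    ----------
    subject_id : str
        Stable subject identifier.
    date : datetime.date
        Calendar date the session belongs to (drives the daily logs).
    data : pandas.DataFrame
        Columns ``t, ax, ay, az, gx, gy, gz, label``; ``t`` in seconds
        from session start, non-decreasing; ``label`` an
        :class:`~rehabhar.classes.ExerciseClass`-valued integer column.
    rate : float
        Nominal sampling rate in Hz (10 unless overridden).
    """

    subject_id: str
    date: datetime.date
    data: pd.DataFrame
    rate: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("a session needs at least one sample")
        missing = [c for c in CSV_HEADER if c not in self.data.columns]
        if missing:
            raise ValueError(f"session data missing columns {missing}")
        t = self.data["t"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        chans = self.data[list(CHANNELS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(chans)):
            raise ValueError("sensor channels contain non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    @property
    def channels(self) -> np.ndarray:
        """(n_samples, 6) float array in fixed (ax..gz) order."""
        return self.data[list(CHANNELS)].to_numpy(dtype=float)


@dataclasses.dataclass
class Window:
    """A 30-sample slice of a session with a single class label.

    ``values`` holds all six channels (time on axis 0); sensor-subset
    selection happens later so one segmentation pass serves every
    ablation arm.  ``segment`` is the id of the contiguous same-label
    run the window starts in, used by leakage-safe fold grouping.
    """

    values: np.ndarray  # (window_len, 6)
    label: ExerciseClass
    subject_id: str
    start: int
    segment: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(CHANNELS):
            raise ValueError(f"window values must be (n, 6), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")


def write_session(session: LabeledSession, path: str | Path) -> Path:
    """Write a session to CSV (header ``t,ax,...,gz,label``).

    Labels are written as class-name strings; floats at full precision
    (``repr``), so a read round-trips bit-exactly.
    """
    path = Path(path)
    out = session.data.loc[:, list(CSV_HEADER)].copy()
    out["label"] = [ExerciseClass(v).name for v in out["label"]]
    out.to_csv(path, index=False, float_format=None)
    return path


def read_session(
    path: str | Path,
    subject_id: str | None = None,
    date: datetime.date | None = None,
    rate: float = DEFAULT_RATE_HZ,
) -> LabeledSession:
    """Read a session CSV written by :func:`write_session`.

    Unknown label strings and non-numeric sensor values are rejected
    with the offending 1-based file line number.  A header-only file is
    an error (a session needs at least one sample).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(CSV_HEADER):
        raise ValueError(
            f"{path}: expected header {','.join(CSV_HEADER)}, got {','.join(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no samples (header-only file)")

    numeric = {}
    for col in ("t",) + CHANNELS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            line = int(bad[0]) + 2  # +1 header, +1 1-based
            raise ValueError(
                f"{path}:{line}: malformed value {df[col].iloc[bad[0]]!r} in column {col!r}"
            )
        numeric[col] = converted.to_numpy(dtype=float)

    valid_names = {c.name for c in ExerciseClass}
    labels = df["label"].to_numpy()
    bad = np.flatnonzero(~np.isin(labels, list(valid_names)))
    if bad.size:
        line = int(bad[0]) + 2
        raise ValueError(
            f"{path}:{line}: unknown label {labels[bad[0]]!r}; "
            f"expected one of {sorted(valid_names)}"
        )

    data = pd.DataFrame(numeric)
    data["label"] = [int(ExerciseClass[name]) for name in labels]
    if subject_id is None:
        subject_id = path.stem
    if date is None:
        date = datetime.date.today()
    return LabeledSession(subject_id=subject_id, date=date, data=data, rate=rate)


def _modal_label(window_labels: np.ndarray) -> ExerciseClass:
    """Majority label of a window; ties go to NO_EXERCISE if it is among
    the leaders, otherwise to the lowest class index."""
    counts = np.bincount(window_labels, minlength=len(ExerciseClass))
    leaders = np.flatnonzero(counts == counts.max())
    return ExerciseClass(int(leaders[0]))  # NO_EXERCISE is index 0


def segment_windows(
    session: LabeledSession,
    window_s: float = 3.0,
    stride_samples: int = 5,
) -> list[Window]:
    """Cut a session into overlapping fixed-length windows.

    Windows start at sample offsets 0, stride, 2*stride, ...; with N
    samples and window length W the count is ``floor((N - W)/stride) + 1``
    for N >= W and 0 otherwise.  Each window's label is the modal
    per-sample label, ties resolved toward NO_EXERCISE (conservative:
    ambiguous time is not credited as exercise).
    """
    if stride_samples <= 0:
        raise ValueError("stride must be a positive sample count")
    w_float = window_s * session.rate
    w = int(round(w_float))
    if abs(w_float - w) > 1e-9 or w < 2:
        raise ValueError(
            f"window_s * rate must be an integer >= 2, got {w_float}"
        )

    n = len(session)
    if n < w:
        return []

    values = session.channels
    labels = session.labels
    # contiguous same-label runs, for leakage-safe (SEGMENT) grouping
    run_id = np.concatenate([[0], np.cumsum(np.diff(labels) != 0)])

    starts = range(0, n - w + 1, stride_samples)
    windows = []
    for s in starts:
        windows.append(
            Window(
                values=values[s : s + w],
                label=_modal_label(labels[s : s + w]),
                subject_id=session.subject_id,
                start=s,
                segment=int(run_id[s]),
            )
        )
    return windows


def segment_sessions(
    sessions: Sequence[LabeledSession],
    window_s: float = 3.0,
    stride_samples: int = 5,
) -> list[Window]:
    """Segment several sessions, offsetting segment ids so runs from
    different sessions never share a group."""
    windows: list[Window] = []
    offset = 0
    for sess in sessions:
        ws = segment_windows(sess, window_s=window_s, stride_samples=stride_samples)
        for w in ws:
            w.segment += offset
        if ws:
            offset = max(w.segment for w in ws) + 1
        windows.extend(ws)
    return windows
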