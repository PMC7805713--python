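"""Engagement-index labels from behavior-interval annotations.

Six target behaviors signal social engagement in a child-robot interaction:
eye-gaze focus, vocalizations, smiling, self-initiated interactions, triadic
interactions, and imitation.  Human coders log them as (behavior, start, stop)
intervals.  At any instant the engagement index is the number of concurrently
active behaviors divided by six, giving seven levels {0, 1/6, ..., 1}; the
integer level*6 is the 7-class label the classifiers predict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntervalError, VocabularyError

BEHAVIORS = (
    "eye_gaze",
    "vocalization",
    "smiling",
    "self_initiated",
    "triadic",
    "imitation",
)
N_BEHAVIORS = len(BEHAVIORS)
N_CLASSES = N_BEHAVIORS + 1

# accept common label spellings seen in event-logging exports
_ALIASES = {
    "eye gaze": "eye_gaze",
    "eye gaze focus": "eye_gaze",
    "gaze": "eye_gaze",
    "vocalizations": "vocalization",
    "smile": "smiling",
    "self-initiated": "self_initiated",
    "self initiated": "self_initiated",
    "self-initiated interaction": "self_initiated",
    "triadic interaction": "triadic",
    "triadic interactions": "triadic",
    "imitations": "imitation",
}


@dataclass(frozen=True)
class BehaviorEvent:
    behavior: str
    start_s: float
    stop_s: float

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise VocabularyError(f"unknown behavior: {self.behavior!r}")
        if not self.stop_s > self.start_s:
            raise IntervalError(
                f"{self.behavior}: stop ({self.stop_s}) must be > start ({self.start_s})"
            )
        if self.start_s < 0:
            raise IntervalError(f"{self.behavior}: negative start {self.start_s}")


def normalize_behavior(name: str) -> str:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in BEHAVIORS:
        raise VocabularyError(f"unknown behavior: {name!r}")
    return key


def merge_events(events: list[BehaviorEvent]) -> list[BehaviorEvent]:
    """Union overlapping/abutting same-behavior intervals.

    A behavior contributes at most 1/6 at any instant, so overlapping logs of
    the same behavior must collapse to one interval before counting.
    """
    out = []
    for b in BEHAVIORS:
        ivs = sorted(
            (e.start_s, e.stop_s) for e in events if e.behavior == b
        )
        merged: list[list[float]] = []
        for s, t in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], t)
            else:
                merged.append([s, t])
        out.extend(BehaviorEvent(b, s, t) for s, t in merged)
    return out


def read_behavior_events(path: str | Path) -> list[BehaviorEvent]:
    """Read a behavior-event CSV export (columns behavior, start_s, stop_s).

    Column-name variants from common event-logging software are accepted
    (Behavior / Start (s) / Stop (s)); extra columns are ignored.  Events of
    the same behavior are merged into their interval union.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise VocabularyError(
            f"{path}: no column among {names}; found {list(df.columns)}"
        )

    bcol = pick("behavior", "behaviour", "behavior type")
    scol = pick("start_s", "start (s)", "start")
    tcol = pick("stop_s", "stop (s)", "stop")
    events = [
        BehaviorEvent(normalize_behavior(str(r[bcol])), float(r[scol]), float(r[tcol]))
        for _, r in df.iterrows()
    ]
    return merge_events(events)


def write_behavior_events(events: list[BehaviorEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.behavior, e.start_s, e.stop_s) for e in events],
        columns=["behavior", "start_s", "stop_s"],
    ).to_csv(path, index=False)


@dataclass
class EngagementSeries:
    """Per-frame engagement level (fraction of active behaviors) and class."""

    level: np.ndarray  # values in {0, 1/6, ..., 1}
    klass: np.ndarray  # int, level*6
    fps: float
    frame_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.level))

    def __len__(self) -> int:
        return len(self.level)


def engagement_series(
    events: list[BehaviorEvent],
    n_frames: int,
    fps: float,
    frame_index: np.ndarray | None = None,
) -> EngagementSeries:
    """Map interval annotations to a per-frame engagement label series.

    Frame t is evaluated at time t/fps; an event [start, stop) covers the
    frame when start <= t/fps < stop (closed-open, so abutting events tile
    without double counting).  Level = active behavior count / 6.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if frame_index is None:
        frame_index = np.arange(n_frames)
    else:
        frame_index = np.asarray(frame_index, dtype=int)
        if len(frame_index) != n_frames:
            raise ValueError("frame_index length must equal n_frames")
    t = frame_index / fps
    count = np.zeros(n_frames, dtype=int)
    for e in merge_events(list(events)):
        count += (t >= e.start_s) & (t < e.stop_s)
    level = count / N_BEHAVIORS
    return EngagementSeries(
        level=level,
        klass=np.rint(level * N_BEHAVIORS).astype(int),
        fps=fps,
        frame_index=frame_index,
    )


def level_histogram(series: EngagementSeries) -> np.ndarray:
    """Counts per engagement class 0..6 (sums to the series length)."""
    if len(series) == 0:
        raise ValueError("empty series")
    return np.bincount(series.klass, minlength=N_CLASSES)
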