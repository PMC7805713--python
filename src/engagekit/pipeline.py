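"""End-to-end chaining of the pipeline stages for one subject.

keypoints -> gap-filled track -> Laban + facial features -> 71-column
feature matrix -> engagement labels -> windowed classifier dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import FeatureMatrix, WindowedDataset, assemble, facial_features, make_windows
from .engagement import BehaviorEvent, EngagementSeries, engagement_series
from .laban import laban_series
from .pose_io import KeypointTrack, fill_gaps


@dataclass
class SubjectData:
    """Everything extracted for one subject."""

    subject_id: str
    group: str
    features: FeatureMatrix
    labels: EngagementSeries
    windows: WindowedDataset


def extract_subject(
    track: KeypointTrack,
    events: list[BehaviorEvent],
    group: str = "",
    window_frames: int = 30,
    seq_len: int = 5,
    max_gap_frames: int = 15,
    time_mode: str = "acceleration",
) -> SubjectData:
    """Run the full feature/label extraction for one subject's track."""
    track = fill_gaps(track, max_gap_frames)
    laban = laban_series(track, window_frames=window_frames, time_mode=time_mode)
    facial = facial_features(track)
    features = assemble(facial, laban)
    n_frames = int(track.frame_index.max()) + 1
    labels = engagement_series(events, n_frames, track.fps)
    windows = make_windows(
        features, labels, seq_len=seq_len, subject_id=track.subject_id, group=group
    )
    return SubjectData(track.subject_id, group, features, labels, windows)
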