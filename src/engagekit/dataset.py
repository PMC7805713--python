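"""Feature-matrix assembly and sliding-window dataset construction.

The classifier input is a 71-dimensional feature vector per frame: x,y
coordinates of 34 facial keypoints (the 12 eye-contour points, 20 lip points
and 2 pupils of the 70-point face model) followed by the three Laban effort
features.  Frames are windowed into short stride-1 sequences (default length
5) whose label is the engagement class of the final frame — a causal
convention that supports streaming prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engagement import EngagementSeries
from .errors import (
    AlignmentError,
    EmptyDatasetError,
    MissingFaceError,
    ParameterError,
    SchemaError,
)
from .laban import LabanSeries
from .pose_io import KeypointTrack

# 70-point face model: 36-41 right eye, 42-47 left eye, 48-67 lips, 68-69 pupils
EYE_POINTS = tuple(range(36, 48))
LIP_POINTS = tuple(range(48, 68))
PUPIL_POINTS = (68, 69)
FACE_POINTS = EYE_POINTS + LIP_POINTS + PUPIL_POINTS  # 34 points
LABAN_COLUMNS = ("space", "weight", "time")
N_FEATURES = 2 * len(FACE_POINTS) + len(LABAN_COLUMNS)  # 71

FACIAL_COLUMNS = tuple(
    f"face{p}_{c}" for p in FACE_POINTS for c in ("x", "y")
)


def facial_features(track: KeypointTrack) -> pd.DataFrame:
    """x,y of the 34 eye/lip/pupil keypoints per frame, indexed by frame.

    Frames where the face was not detected at all become NaN rows (dropped at
    assembly); a track with no detected face anywhere is an error.
    """
    pts = track.face[:, FACE_POINTS, :]
    absent = ((pts[:, :, 2] <= 0) & (pts[:, :, 0] == 0) & (pts[:, :, 1] == 0)).all(
        axis=1
    )
    if absent.all():
        raise MissingFaceError(f"{track.subject_id}: face absent in every frame")
    xy = pts[:, :, :2].reshape(len(track), -1).astype(float)
    xy[absent] = np.nan
    return pd.DataFrame(xy, index=track.frame_index, columns=list(FACIAL_COLUMNS))


@dataclass
class FeatureMatrix:
    """T x 71 feature matrix aligned to original video frame indices."""

    values: np.ndarray
    column_names: tuple[str, ...]
    frame_index: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise SchemaError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.column_names) != N_FEATURES:
            raise SchemaError("column_names length mismatch")

    def __len__(self) -> int:
        return len(self.frame_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.frame_index, columns=list(self.column_names)
        )


def assemble(facial: pd.DataFrame, laban: LabanSeries) -> FeatureMatrix:
    """Concatenate facial columns with the Laban series, aligned by frame.

    Rows where either side is missing (absent frame or NaN feature) are
    dropped; zero overlap is an alignment error.
    """
    lab = laban.to_frame().set_index("frame")
    joined = facial.join(lab, how="inner")
    joined = joined.dropna()
    if joined.empty:
        raise AlignmentError("no overlapping complete frames between facial and Laban features")
    cols = tuple(FACIAL_COLUMNS) + LABAN_COLUMNS
    return FeatureMatrix(
        values=joined[list(cols)].to_numpy(),
        column_names=cols,
        frame_index=joined.index.to_numpy(),
    )


@dataclass
class WindowedDataset:
    """N sequences of L frames x 71 features with 7-class labels."""

    sequences: np.ndarray  # (N, L, 71)
    labels: np.ndarray  # (N,) int in 0..6
    subject_id: str = "subject"
    group: str = ""  # "TD" | "ASD" | ""
    end_frames: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise SchemaError("sequences and labels length mismatch")
        if self.end_frames is None:
            self.end_frames = np.arange(len(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def seq_len(self) -> int:
        return self.sequences.shape[1]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return replace(
            self,
            sequences=self.sequences[idx],
            labels=self.labels[idx],
            end_frames=self.end_frames[idx],
        )


def make_windows(
    features: FeatureMatrix,
    labels: EngagementSeries,
    seq_len: int = 5,
    subject_id: str | None = None,
    group: str = "",
) -> WindowedDataset:
    """Stride-1 sliding windows within each contiguous frame segment.

    Windows never span a gap between segments; each window is labelled with
    the engagement class of its final frame.
    """
    if seq_len < 1:
        raise ParameterError("seq_len must be >= 1")
    label_map = pd.Series(labels.klass, index=labels.frame_index)
    fidx = features.frame_index
    missing = ~np.isin(fidx, labels.frame_index)
    if missing.any():
        raise AlignmentError(
            f"{missing.sum()} feature frames lack an engagement label"
        )
    y_frames = label_map.loc[fidx].to_numpy()

    breaks = np.flatnonzero(np.diff(fidx) > 1) + 1
    edges = [0, *breaks.tolist(), len(fidx)]
    seqs, ys, ends = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < seq_len:
            continue
        X = features.values[a:b]
        sw = np.lib.stride_tricks.sliding_window_view(X, (seq_len, X.shape[1]))
        seqs.append(sw[:, 0].copy())
        ys.append(y_frames[a + seq_len - 1 : b])
        ends.append(fidx[a + seq_len - 1 : b])
    if not seqs:
        raise EmptyDatasetError(f"no contiguous segment of >= {seq_len} frames")
    return WindowedDataset(
        sequences=np.concatenate(seqs),
        labels=np.concatenate(ys),
        subject_id=subject_id or "subject",
        group=group,
        end_frames=np.concatenate(ends),
    )


def split(
    dataset: WindowedDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    val_fraction: float = 0.1,
    blocked: bool = False,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Random (train, validation, test) partition of windows.

    test_fraction of all windows go to test; val_fraction of the remainder to
    validation (floor rounding).  ``blocked=True`` splits by time instead of
    at random, avoiding leakage between temporally adjacent windows; the
    random split is the default protocol.
    """
    if not 0 < test_fraction < 1:
        raise ParameterError(f"test_fraction {test_fraction} outside (0, 1)")
    if not 0 <= val_fraction < 1:
        raise ParameterError(f"val_fraction {val_fraction} outside [0, 1)")
    n = len(dataset)
    if n < 10:
        raise ParameterError(f"need >= 10 windows to split, have {n}")
    if blocked:
        order = np.argsort(dataset.end_frames, kind="stable")
    else:
        order = np.random.default_rng(seed).permutation(n)
    n_test = int(np.floor(n * test_fraction))
    n_val = int(np.floor((n - n_test) * val_fraction))
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    return dataset.subset(train_idx), dataset.subset(val_idx), dataset.subset(test_idx)


def concat_datasets(datasets: list[WindowedDataset], subject_id: str = "pooled", group: str = "") -> WindowedDataset:
    """Pool windows from several subjects (group/combined models)."""
    if not datasets:
        raise EmptyDatasetError("no datasets to pool")
    L = {d.seq_len for d in datasets}
    if len(L) != 1:
        raise SchemaError(f"mixed sequence lengths {L}")
    return WindowedDataset(
        sequences=np.concatenate([d.sequences for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        subject_id=subject_id,
        group=group,
        end_frames=np.concatenate([d.end_frames for d in datasets]),
    )


def zscore(dataset: WindowedDataset) -> WindowedDataset:
    """Optional per-feature standardization (off by default in the pipeline)."""
    flat = dataset.sequences.reshape(-1, dataset.sequences.shape[-1])
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    return replace(dataset, sequences=(dataset.sequences - mu) / sd)


def save_dataset(dataset: WindowedDataset, path: str | Path) -> None:
    """Write sequences/labels to an .npz container plus a CSV manifest."""
    path = Path(path)
    np.savez_compressed(
        path,
        sequences=dataset.sequences,
        labels=dataset.labels,
        end_frames=dataset.end_frames,
        subject_id=np.array(dataset.subject_id),
        group=np.array(dataset.group),
    )
    counts = np.bincount(dataset.labels, minlength=7)
    manifest = pd.DataFrame(
        [
            {
                "subject": dataset.subject_id,
                "group": dataset.group,
                "n_windows": len(dataset),
                "seq_len": dataset.seq_len,
                **{f"class_{k}": counts[k] for k in range(7)},
            }
        ]
    )
    manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_dataset(path: str | Path) -> WindowedDataset:
    with np.load(path, allow_pickle=False) as z:
        return WindowedDataset(
            sequences=z["sequences"],
            labels=z["labels"],
            end_frames=z["end_frames"],
            subject_id=str(z["subject_id"]),
            group=str(z["group"]),
        )
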