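"""Reading, cleaning and time-aligning 2D keypoint streams.

The raw input is the output of an upstream 2D pose estimator: one record per
video frame, each holding zero or more person detections with 25 body
keypoints (BODY_25 layout) and 70 face keypoints, every point an
(x, y, confidence) triple in image pixel coordinates (origin top-left,
y down).  This module turns those multi-person records into a
single-subject :class:`KeypointTrack` suitable for kinematic feature
extraction: it selects one person per frame by positional continuity,
linearly interpolates short dropout gaps, and splits the track into
contiguous segments at long gaps.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyTrackError, ParseError, SchemaError

N_BODY = 25
N_FACE = 70

# BODY_25 indices used downstream
NOSE, NECK = 0, 1
R_SHOULDER, R_ELBOW, R_WRIST = 2, 3, 4
L_SHOULDER, L_ELBOW, L_WRIST = 5, 6, 7
MID_HIP = 8


@dataclass
class PoseFrame:
    """A single frame of one person: 25 body + 70 face (x, y, conf) triples."""

    frame_index: int
    body: np.ndarray  # (25, 3)
    face: np.ndarray  # (70, 3)

    def __post_init__(self):
        self.body = np.asarray(self.body, dtype=float)
        self.face = np.asarray(self.face, dtype=float)
        if self.body.shape != (N_BODY, 3):
            raise SchemaError(
                f"frame {self.frame_index}: expected {N_BODY} body keypoints, "
                f"got shape {self.body.shape}"
            )
        if self.face.shape != (N_FACE, 3):
            raise SchemaError(
                f"frame {self.frame_index}: expected {N_FACE} face keypoints, "
                f"got shape {self.face.shape}"
            )


@dataclass
class RawFrame:
    """One input record: all person candidates detected in a frame."""

    frame_index: int
    people: list[PoseFrame] = field(default_factory=list)


@dataclass
class KeypointTrack:
    """Single-subject keypoint time series.

    ``frame_index`` is strictly increasing; holes in it mark frames where the
    subject was absent.  After :func:`fill_gaps`, holes no longer than the gap
    limit are filled with interpolated frames flagged in ``gap_mask``; longer
    holes remain and define segment boundaries (see :meth:`segments`).
    """

    subject_id: str
    fps: float
    frame_index: np.ndarray  # (T,) int
    body: np.ndarray  # (T, 25, 3)
    face: np.ndarray  # (T, 70, 3)
    gap_mask: np.ndarray  # (T,) bool, True = interpolated frame

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.body = np.asarray(self.body, dtype=float)
        self.face = np.asarray(self.face, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        d = np.diff(self.frame_index)
        if len(d) and (d <= 0).any():
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_index)

    def frame(self, i: int) -> PoseFrame:
        return PoseFrame(int(self.frame_index[i]), self.body[i], self.face[i])

    def segments(self) -> list[slice]:
        """Contiguous runs of frame_index (no holes), as row slices."""
        if len(self) == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.frame_index) > 1) + 1
        edges = [0, *breaks.tolist(), len(self)]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _parse_person(obj: dict, frame_index: int) -> PoseFrame:
    pose = np.asarray(obj.get("pose_keypoints_2d", []), dtype=float)
    face = np.asarray(obj.get("face_keypoints_2d", []), dtype=float)
    if pose.size != N_BODY * 3:
        raise SchemaError(
            f"frame {frame_index}: pose_keypoints_2d has {pose.size} values, "
            f"expected {N_BODY * 3}"
        )
    if face.size == 0:
        face = np.zeros(N_FACE * 3)
    if face.size != N_FACE * 3:
        raise SchemaError(
            f"frame {frame_index}: face_keypoints_2d has {face.size} values, "
            f"expected {N_FACE * 3}"
        )
    return PoseFrame(frame_index, pose.reshape(N_BODY, 3), face.reshape(N_FACE, 3))


_FRAME_RE = re.compile(r"(\d+)_keypoints\.json$")


def read_keypoint_stream(source: str | Path) -> list[RawFrame]:
    """Read a keypoint stream into raw multi-person frames.

    ``source`` may be a directory of per-frame JSON files (each
    ``{"people": [{"pose_keypoints_2d": [...], "face_keypoints_2d": [...]}]}``,
    frame index taken from the ``*_<index>_keypoints.json`` filename) or a
    single flat CSV with columns frame, person, part, point_id, x, y, conf.
    Frames are returned ordered by frame index, people in input order.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if source.is_dir():
        frames = []
        for path in sorted(source.glob("*_keypoints.json")):
            m = _FRAME_RE.search(path.name)
            if m is None:
                raise ParseError(f"cannot extract frame index from {path.name}")
            idx = int(m.group(1))
            try:
                doc = json.loads(path.read_text())
            except json.JSONDecodeError as e:
                raise ParseError(f"frame {idx}: malformed JSON ({e})") from e
            people = [_parse_person(p, idx) for p in doc.get("people", [])]
            frames.append(RawFrame(idx, people))
        frames.sort(key=lambda f: f.frame_index)
        return frames
    return _read_csv_stream(source)


def _read_csv_stream(path: Path) -> list[RawFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "part", "point_id", "x", "y", "conf"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    if "person" not in df.columns:
        df = df.assign(person=0)
    frames = []
    for idx, fgroup in df.groupby("frame", sort=True):
        people = []
        for _, pgroup in fgroup.groupby("person", sort=True):
            body = np.zeros((N_BODY, 3))
            face = np.zeros((N_FACE, 3))
            for part, arr, n in (("body", body, N_BODY), ("face", face, N_FACE)):
                rows = pgroup[pgroup["part"] == part]
                ids = rows["point_id"].to_numpy(dtype=int)
                if len(ids) and (ids.min() < 0 or ids.max() >= n):
                    raise SchemaError(f"frame {idx}: {part} point_id out of range")
                arr[ids] = rows[["x", "y", "conf"]].to_numpy(dtype=float)
            people.append(PoseFrame(int(idx), body, face))
        frames.append(RawFrame(int(idx), people))
    return frames


def _mean_position(p: PoseFrame) -> np.ndarray | None:
    pts = np.vstack([p.body, p.face])
    ok = pts[:, 2] > 0
    if not ok.any():
        return None
    return pts[ok, :2].mean(axis=0)


def select_subject(
    raw_frames: list[RawFrame],
    fps: float,
    subject_id: str = "subject",
    policy: str = "continuity",
) -> KeypointTrack:
    """Pick one person per frame by greedy positional continuity.

    The upstream estimator's own person-ID assignment is not trusted (it is
    unreliable when several people share the scene), so the subject is tracked
    by proximity: the first detected frame seeds with the candidate of largest
    mean confidence, and every later frame picks the candidate whose mean
    keypoint position is nearest the previous selection.  Frames with no
    candidates are skipped (absent subject); tracking resumes from the last
    selected position.
    """
    if policy != "continuity":
        raise ValueError(f"unknown tracking policy: {policy}")
    if not raw_frames:
        raise EmptyTrackError("no frames in stream")

    anchor = None
    idx, bodies, faces = [], [], []
    for rf in raw_frames:
        candidates = [(p, _mean_position(p)) for p in rf.people]
        candidates = [(p, pos) for p, pos in candidates if pos is not None]
        if not candidates:
            continue
        if anchor is None:
            chosen = max(
                candidates,
                key=lambda c: float(
                    np.mean(np.concatenate([c[0].body[:, 2], c[0].face[:, 2]]))
                ),
            )
        else:
            chosen = min(candidates, key=lambda c: float(np.linalg.norm(c[1] - anchor)))
        person, anchor = chosen
        idx.append(rf.frame_index)
        bodies.append(person.body)
        faces.append(person.face)

    if not idx:
        raise EmptyTrackError("subject absent in every frame")
    return KeypointTrack(
        subject_id=subject_id,
        fps=fps,
        frame_index=np.array(idx),
        body=np.stack(bodies),
        face=np.stack(faces),
        gap_mask=np.zeros(len(idx), dtype=bool),
    )


def _interp_points(arr: np.ndarray, max_gap: int) -> np.ndarray:
    """Interpolate per-point dropouts (conf<=0) over time within one segment.

    Interior invalid runs of length <= max_gap get linearly interpolated x,y
    with conf left at 0; longer runs and edge runs are left untouched.
    """
    out = arr.copy()
    T = arr.shape[0]
    for k in range(arr.shape[1]):
        valid = arr[:, k, 2] > 0
        if valid.all() or not valid.any():
            continue
        vi = np.flatnonzero(valid)
        t = np.arange(T)
        # find interior invalid runs
        invalid = ~valid
        starts = np.flatnonzero(invalid & ~np.roll(invalid, 1))
        if invalid[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        for s in starts:
            e = s
            while e < T and invalid[e]:
                e += 1
            run = e - s
            if s == 0 or e == T or run > max_gap:
                continue
            out[s:e, k, 0] = np.interp(t[s:e], vi, arr[vi, k, 0])
            out[s:e, k, 1] = np.interp(t[s:e], vi, arr[vi, k, 1])
    return out


def fill_gaps(track: KeypointTrack, max_gap_frames: int = 15) -> KeypointTrack:
    """Fill whole-frame dropouts of <= ``max_gap_frames`` by linear interpolation.

    Interpolated frames are flagged in ``gap_mask`` and carry confidence 0.
    Longer holes are left open, splitting the track into segments.  Per-point
    dropouts (conf <= 0 inside otherwise detected frames) are interpolated the
    same way within each segment.  Idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if len(track) == 0:
        return track

    idx = track.frame_index
    new_idx, new_body, new_face, new_mask = [], [], [], []
    for i in range(len(track)):
        new_idx.append(idx[i])
        new_body.append(track.body[i])
        new_face.append(track.face[i])
        new_mask.append(track.gap_mask[i])
        if i + 1 < len(track):
            hole = idx[i + 1] - idx[i] - 1
            if 0 < hole <= max_gap_frames:
                for j in range(1, hole + 1):
                    w = j / (hole + 1)
                    b = (1 - w) * track.body[i] + w * track.body[i + 1]
                    f = (1 - w) * track.face[i] + w * track.face[i + 1]
                    b[:, 2] = 0.0
                    f[:, 2] = 0.0
                    new_idx.append(idx[i] + j)
                    new_body.append(b)
                    new_face.append(f)
                    new_mask.append(True)

    out = KeypointTrack(
        subject_id=track.subject_id,
        fps=track.fps,
        frame_index=np.array(new_idx),
        body=np.stack(new_body),
        face=np.stack(new_face),
        gap_mask=np.array(new_mask, dtype=bool),
    )
    for seg in out.segments():
        out.body[seg] = _interp_points(out.body[seg], max_gap_frames)
        out.face[seg] = _interp_points(out.face[seg], max_gap_frames)
    return out


def normalize_by_shoulder_width(track: KeypointTrack) -> KeypointTrack:
    """Optional coordinate normalization by median inter-shoulder distance.

    Off by default in the pipeline; raw pixel coordinates are the working
    units.  Useful when comparing subjects filmed at different distances.
    """
    ls = track.body[:, L_SHOULDER, :2]
    rs = track.body[:, R_SHOULDER, :2]
    ok = (track.body[:, L_SHOULDER, 2] > 0) & (track.body[:, R_SHOULDER, 2] > 0)
    if not ok.any():
        raise EmptyTrackError("no frames with both shoulders detected")
    scale = float(np.median(np.linalg.norm(ls[ok] - rs[ok], axis=1)))
    if scale <= 0:
        raise ValueError("degenerate shoulder width")
    body = track.body.copy()
    face = track.face.copy()
    body[:, :, :2] /= scale
    face[:, :, :2] /= scale
    return replace(track, body=body, face=face)


# ---------------------------------------------------------------------------
# serialization

def write_track_csv(track: KeypointTrack, path: str | Path) -> None:
    """Serialize a track to a flat CSV (round-trips coordinates exactly)."""
    rows = []
    for part, arr, n in (("body", track.body, N_BODY), ("face", track.face, N_FACE)):
        t_col = np.repeat(track.frame_index, n)
        pid = np.tile(np.arange(n), len(track))
        flat = arr.reshape(-1, 3)
        rows.append(
            pd.DataFrame(
                {
                    "frame": t_col,
                    "part": part,
                    "point_id": pid,
                    "x": flat[:, 0],
                    "y": flat[:, 1],
                    "conf": flat[:, 2],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    header = f"# subject_id={track.subject_id} fps={track.fps!r}\n"
    gaps = ",".join(str(int(i)) for i in track.frame_index[track.gap_mask])
    header += f"# gap_frames={gaps}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")  # exact float round-trip


def read_track_csv(path: str | Path) -> KeypointTrack:
    """Inverse of :func:`write_track_csv`."""
    with open(path) as fh:
        meta = fh.readline().strip().lstrip("# ")
        gap_line = fh.readline().strip().lstrip("# ")
        df = pd.read_csv(fh, float_precision="round_trip")
    kv = dict(item.split("=", 1) for item in meta.split())
    gap_frames = set()
    if gap_line.startswith("gap_frames="):
        payload = gap_line.split("=", 1)[1]
        if payload:
            gap_frames = {int(s) for s in payload.split(",")}
    idx = np.sort(df["frame"].unique())
    pos = {f: i for i, f in enumerate(idx)}
    body = np.zeros((len(idx), N_BODY, 3))
    face = np.zeros((len(idx), N_FACE, 3))
    for part, arr in (("body", body), ("face", face)):
        sub = df[df["part"] == part]
        rows = sub["frame"].map(pos).to_numpy(dtype=int)
        arr[rows, sub["point_id"].to_numpy(dtype=int)] = sub[
            ["x", "y", "conf"]
        ].to_numpy(dtype=float)
    return KeypointTrack(
        subject_id=kv["subject_id"],
        fps=float(kv["fps"]),
        frame_index=idx,
        body=body,
        face=face,
        gap_mask=np.array([f in gap_frames for f in idx], dtype=bool),
    )


def write_openpose_dir(track: KeypointTrack, out_dir: str | Path, prefix: str = "video") -> None:
    """Emit one JSON file per frame in the upstream estimator's dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(len(track)):
        doc = {
            "version": 1.3,
            "people": [
                {
                    "person_id": [-1],
                    "pose_keypoints_2d": track.body[i].ravel().tolist(),
                    "face_keypoints_2d": track.face[i].ravel().tolist(),
                }
            ],
        }
        name = f"{prefix}_{int(track.frame_index[i]):012d}_keypoints.json"
        (out_dir / name).write_text(json.dumps(doc))
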