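"""Shared fixtures: hand-built tracks and a small synthetic subject."""

from __future__ import annotations

import numpy as np
import pytest

from engagekit.pose_io import (
    KeypointTrack,
    L_ELBOW,
    L_SHOULDER,
    L_WRIST,
    MID_HIP,
    N_BODY,
    N_FACE,
    NECK,
    PoseFrame,
    R_ELBOW,
    R_SHOULDER,
    R_WRIST,
)


def body_from_points(points: dict[int, tuple[float, float]], conf: float = 0.9) -> np.ndarray:
    """(25,3) body array with the given keypoints present, others absent."""
    body = np.zeros((N_BODY, 3))
    for idx, (x, y) in points.items():
        body[idx] = (x, y, conf)
    return body


def make_frame(points: dict[int, tuple[float, float]], frame_index: int = 0) -> PoseFrame:
    return PoseFrame(frame_index, body_from_points(points), np.zeros((N_FACE, 3)))


UNIT_SQUARE_ARMS = {
    L_SHOULDER: (0.0, 1.0),
    R_SHOULDER: (1.0, 1.0),
    L_WRIST: (0.0, 0.0),
    R_WRIST: (1.0, 0.0),
}


def make_track(
    bodies: list[np.ndarray],
    fps: float = 30.0,
    frame_index: np.ndarray | None = None,
    faces: list[np.ndarray] | None = None,
    subject_id: str = "t",
) -> KeypointTrack:
    T = len(bodies)
    if frame_index is None:
        frame_index = np.arange(T)
    if faces is None:
        face = np.zeros((N_FACE, 3))
        face[:, 0] = np.linspace(300, 340, N_FACE)
        face[:, 1] = np.linspace(140, 180, N_FACE)
        face[:, 2] = 0.8
        faces = [face] * T
    return KeypointTrack(
        subject_id=subject_id,
        fps=fps,
        frame_index=np.asarray(frame_index),
        body=np.stack(bodies),
        face=np.stack(faces),
        gap_mask=np.zeros(T, dtype=bool),
    )


def make_elbow_track(theta: np.ndarray, fps: float = 30.0) -> KeypointTrack:
    """Track whose left-elbow angle follows a prescribed series exactly.

    Shoulder at origin, elbow straight below; the wrist rotates around the
    elbow so the angle between upper-arm and forearm equals theta[t].
    """
    bodies = []
    for th in theta:
        pts = {
            NECK: (0.0, -10.0),
            MID_HIP: (0.0, 100.0),
            L_SHOULDER: (0.0, 0.0),
            L_ELBOW: (0.0, 50.0),
            L_WRIST: (45.0 * np.sin(th), 50.0 + 45.0 * np.cos(th)),
            R_SHOULDER: (-30.0, 0.0),
            R_ELBOW: (-30.0, 50.0),
            R_WRIST: (-30.0, 95.0),
        }
        bodies.append(body_from_points(pts))
    return make_track(bodies, fps=fps)


def static_arm_bodies(n: int, scale: float = 100.0) -> list[np.ndarray]:
    """n identical frames of a full upper body with unit-square arms x scale."""
    pts = {
        NECK: (0.5 * scale, 0.9 * scale),
        MID_HIP: (0.5 * scale, -0.5 * scale),
        L_SHOULDER: (0.0, 1.0 * scale),
        R_SHOULDER: (1.0 * scale, 1.0 * scale),
        L_ELBOW: (0.0, 0.5 * scale),
        R_ELBOW: (1.0 * scale, 0.5 * scale),
        L_WRIST: (0.0, 0.0),
        R_WRIST: (1.0 * scale, 0.0),
    }
    return [body_from_points(pts)] * n


@pytest.fixture(scope="session")
def synthetic_subject():
    """A small synthetic subject shared by dataset/model tests."""
    from engagekit.pipeline import extract_subject
    from engagekit.synthetic import SyntheticConfig, generate_subject

    cfg = SyntheticConfig(n_subjects=1, n_td=1, n_frames=3000, seed=11)
    track, events, truth = generate_subject(cfg, seed=11, subject_id="S01")
    sub = extract_subject(track, events, group="TD")
    return cfg, track, events, truth, sub
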