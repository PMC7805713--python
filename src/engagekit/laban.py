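"""Laban effort features (space, weight, time) from upper-body keypoints.

Laban Movement Analysis describes movement dynamics through Effort qualities.
Three of them are computed here from 2D upper-body keypoints:

* **space** — the planar extent of the arm configuration, measured as the sum
  of the two triangle areas spanned by the shoulder/hand vectors:
  ``0.5|a||d|sin(th1) + 0.5|c||b|sin(th2)`` where ``a`` runs left shoulder to
  left hand, ``b`` right shoulder to left shoulder, ``c`` right hand to right
  shoulder, ``d`` left hand to right hand.  For a convex, consistently ordered
  arm quadrilateral this equals its polygon area.  Units: pixels^2.
* **weight** — a torque-like magnitude of movement power, summed over joints:
  ``sum_i L_i^2 * omega_i^2 * sin(theta_i) * mass_i``.  Units: px^2 rad^2/s^2.
* **time** — movement urgency, summed over joints as the magnitude of angular
  acceleration ``sum_i |omega_dot_i|``.  Units: rad/s^2.

"Hand" keypoints are the wrists (no reliable finger tracking in the upstream
data).  The joint set is both shoulders and both elbows, the upper-body joints
with well-defined 2D angles.  All masses default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingKeypointError, TooShortError
from .pose_io import (
    KeypointTrack,
    L_ELBOW,
    L_SHOULDER,
    L_WRIST,
    MID_HIP,
    NECK,
    PoseFrame,
    R_ELBOW,
    R_SHOULDER,
    R_WRIST,
)

JOINTS = ("left_shoulder", "right_shoulder", "left_elbow", "right_elbow")

# joint -> (angle arm: (p0, vertex, p1) giving vectors vertex->p0, vertex->p1,
#           segment for L: (j0, j1))
_JOINT_DEF = {
    # shoulder angle: torso vector (neck->mid-hip) vs upper arm (shoulder->elbow)
    "left_shoulder": ((NECK, MID_HIP), (L_SHOULDER, L_ELBOW), (L_SHOULDER, L_ELBOW)),
    "right_shoulder": ((NECK, MID_HIP), (R_SHOULDER, R_ELBOW), (R_SHOULDER, R_ELBOW)),
    # elbow angle: upper arm (shoulder->elbow) vs forearm (elbow->wrist)
    "left_elbow": ((L_SHOULDER, L_ELBOW), (L_ELBOW, L_WRIST), (L_ELBOW, L_WRIST)),
    "right_elbow": ((R_SHOULDER, R_ELBOW), (R_ELBOW, R_WRIST), (R_ELBOW, R_WRIST)),
}

_ARM_POINTS = {
    "left_shoulder": L_SHOULDER,
    "right_shoulder": R_SHOULDER,
    "left_hand": L_WRIST,
    "right_hand": R_WRIST,
}


def _present(pts: np.ndarray) -> np.ndarray:
    """A keypoint counts as detected unless conf<=0 with x=y=0 (absent code)."""
    return ~((pts[..., 2] <= 0) & (pts[..., 0] == 0) & (pts[..., 1] == 0))


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


@dataclass
class ArmGeometry:
    """The four arm vectors and two in-between angles of the space feature."""

    a_vec: np.ndarray  # left shoulder -> left hand
    b_vec: np.ndarray  # right shoulder -> left shoulder
    c_vec: np.ndarray  # right hand -> right shoulder
    d_vec: np.ndarray  # left hand -> right hand
    theta1: float  # angle(a, d), radians in [0, pi]; nan when degenerate
    theta2: float  # angle(c, b)
    degenerate: bool = False


def arm_geometry(frame: PoseFrame) -> ArmGeometry:
    """Vectors and angles of the arm quadrilateral for one frame."""
    pts = {}
    for name, idx in _ARM_POINTS.items():
        p = frame.body[idx]
        if not _present(p):
            raise MissingKeypointError(name)
        pts[name] = p[:2]
    a = pts["left_hand"] - pts["left_shoulder"]
    b = pts["left_shoulder"] - pts["right_shoulder"]
    c = pts["right_shoulder"] - pts["right_hand"]
    d = pts["right_hand"] - pts["left_hand"]
    th1, th2 = _angle(a, d), _angle(c, b)
    return ArmGeometry(
        a, b, c, d, th1, th2, degenerate=bool(np.isnan(th1) or np.isnan(th2))
    )


def space(frame: PoseFrame) -> float:
    """Space effort of one frame: sum of the two arm triangle areas (px^2)."""
    g = arm_geometry(frame)

    def tri(u, v):
        # 0.5*|u||v|sin(angle) == half the magnitude of the 2D cross product
        return 0.5 * abs(u[0] * v[1] - u[1] * v[0])

    return tri(g.a_vec, g.d_vec) + tri(g.c_vec, g.b_vec)


def _space_series(track: KeypointTrack) -> np.ndarray:
    b = track.body
    ok = (
        _present(b[:, L_SHOULDER])
        & _present(b[:, R_SHOULDER])
        & _present(b[:, L_WRIST])
        & _present(b[:, R_WRIST])
    )
    ls, rs = b[:, L_SHOULDER, :2], b[:, R_SHOULDER, :2]
    lh, rh = b[:, L_WRIST, :2], b[:, R_WRIST, :2]
    a, d = lh - ls, rh - lh
    c, bb = rs - rh, ls - rs
    cross = lambda u, v: u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    s = 0.5 * np.abs(cross(a, d)) + 0.5 * np.abs(cross(c, bb))
    return np.where(ok, s, np.nan)


@dataclass
class JointKinematics:
    """Angle, angular velocity/acceleration and segment length of one joint."""

    joint_id: str
    theta: np.ndarray  # rad, unwrapped
    omega: np.ndarray  # rad/s
    omega_dot: np.ndarray  # rad/s^2
    L: np.ndarray  # segment length, px
    mass: float = 1.0


def _differentiate(theta: np.ndarray, fps: float, segments: list[slice]) -> tuple[np.ndarray, np.ndarray]:
    """Central differences within each segment, one-sided at segment ends."""
    omega = np.full_like(theta, np.nan)
    omega_dot = np.full_like(theta, np.nan)
    dt = 1.0 / fps
    for seg in segments:
        th = theta[seg]
        if len(th) < 3:
            raise TooShortError(
                f"segment of {len(th)} frames; need >= 3 for differentiation"
            )
        th = np.unwrap(th)
        w = np.gradient(th, dt)
        omega[seg] = w
        omega_dot[seg] = np.gradient(w, dt)
    return omega, omega_dot


def joint_kinematics(track: KeypointTrack, joint_id: str, mass: float = 1.0) -> JointKinematics:
    """Per-frame angle theta, omega = d(theta)/dt and omega_dot for one joint.

    Shoulder angles are measured between the torso vector (neck to mid-hip)
    and the upper arm; elbow angles between upper arm and forearm.  Angles are
    unwrapped before finite differencing so that crossings of 0/pi do not
    produce spurious velocity spikes.
    """
    if joint_id not in _JOINT_DEF:
        raise ValueError(f"unknown joint: {joint_id}")
    (u0, u1), (v0, v1), (l0, l1) = _JOINT_DEF[joint_id]
    b = track.body
    T = len(track)
    theta = np.full(T, np.nan)
    L = np.full(T, np.nan)
    needed = {u0, u1, v0, v1}
    ok = np.all([_present(b[:, j]) for j in needed], axis=0)
    u = b[:, u1, :2] - b[:, u0, :2]
    v = b[:, v1, :2] - b[:, v0, :2]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    nz = ok & (nu > 0) & (nv > 0)
    cosang = np.clip(np.sum(u * v, axis=1)[nz] / (nu[nz] * nv[nz]), -1.0, 1.0)
    theta[nz] = np.arccos(cosang)
    L[ok] = np.linalg.norm(b[:, l1, :2] - b[:, l0, :2], axis=1)[ok]
    omega, omega_dot = _differentiate(theta, track.fps, track.segments())
    return JointKinematics(joint_id, theta, omega, omega_dot, L, mass)


def weight(kinematics: list[JointKinematics], frame_index: int) -> float:
    """Weight effort at one frame: sum_i L^2 omega^2 sin(theta) * mass."""
    return float(
        sum(
            k.L[frame_index] ** 2
            * k.omega[frame_index] ** 2
            * np.sin(k.theta[frame_index])
            * k.mass
            for k in kinematics
        )
    )


def time_feature(
    kinematics: list[JointKinematics], frame_index: int, mode: str = "acceleration"
) -> float:
    """Time effort at one frame: sum over joints of |omega_dot| (default).

    ``mode="velocity"`` sums |omega| instead, for the alternative reading of
    the effort definition in which time tracks speed rather than urgency.
    """
    if mode == "acceleration":
        return float(sum(abs(k.omega_dot[frame_index]) for k in kinematics))
    if mode == "velocity":
        return float(sum(abs(k.omega[frame_index]) for k in kinematics))
    raise ValueError(f"unknown time mode: {mode}")


@dataclass
class LabanSeries:
    """Windowed space/weight/time series aligned with a track's frames."""

    space: np.ndarray
    weight: np.ndarray
    time: np.ndarray
    window_frames: int
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.space)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "space": self.space,
                "weight": self.weight,
                "time": self.time,
            }
        )


def _trailing_mean(x: np.ndarray, window: int, segments: list[slice]) -> np.ndarray:
    """Trailing moving mean of available (non-NaN) values, restarted per segment."""
    import pandas as pd

    out = np.full_like(x, np.nan)
    for seg in segments:
        out[seg] = (
            pd.Series(x[seg]).rolling(window, min_periods=1).mean().to_numpy()
        )
    return out


def laban_series(
    track: KeypointTrack,
    window_frames: int = 30,
    time_mode: str = "acceleration",
) -> LabanSeries:
    """Compute the three effort features with trailing-window aggregation.

    Instantaneous space/weight/time are evaluated per frame, then each output
    frame t carries the mean over the trailing window [t-window_frames+1, t]
    (clipped to the start of the frame's contiguous segment, so early frames
    average whatever is available).  The default 30-frame window is one second
    at 30 fps, short enough to track rapid movement changes.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if len(track) < 3:
        raise TooShortError(f"track has {len(track)} frames; need >= 3")
    kins = [joint_kinematics(track, j) for j in JOINTS]
    sp = _space_series(track)
    with np.errstate(invalid="ignore"):
        wt = sum(k.L**2 * k.omega**2 * np.sin(k.theta) * k.mass for k in kins)
        if time_mode == "acceleration":
            tm = sum(np.abs(k.omega_dot) for k in kins)
        elif time_mode == "velocity":
            tm = sum(np.abs(k.omega) for k in kins)
        else:
            raise ValueError(f"unknown time mode: {time_mode}")
    segs = track.segments()
    return LabanSeries(
        space=_trailing_mean(sp, window_frames, segs),
        weight=_trailing_mean(wt, window_frames, segs),
        time=_trailing_mean(tm, window_frames, segs),
        window_frames=window_frames,
        frame_index=track.frame_index.copy(),
    )
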