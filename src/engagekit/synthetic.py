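"""Synthetic keypoint streams and annotations with known engagement structure.

The study's recordings are not redistributable, so this module emulates their
statistical shape: a child moving in front of a camera, tracked as 25 body +
70 face 2D keypoints at 30 fps, with behavior intervals logged by annotators.
Behavior events are drawn first (an alternating on/off renewal process per
behavior); the number of concurrently active behaviors — the engagement class
— then drives the kinematic regime: higher engagement means strictly larger
arm-swing amplitude (and livelier facial-keypoint motion), which makes the
classes learnable by construction.  Active smiling additionally widens the
lip-keypoint spread so the facial channels carry behavior-specific signal.

The generator emits the same on-disk formats the readers consume, so the
whole pipeline can be exercised round-trip without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engagement import (
    BEHAVIORS,
    BehaviorEvent,
    EngagementSeries,
    engagement_series,
    merge_events,
)
from .errors import ConfigError
from .pose_io import (
    KeypointTrack,
    L_ELBOW,
    L_SHOULDER,
    L_WRIST,
    MID_HIP,
    N_BODY,
    N_FACE,
    NECK,
    NOSE,
    R_ELBOW,
    R_SHOULDER,
    R_WRIST,
)

# (mean on-duration s, mean off-duration s) per behavior; chosen so a session
# spends most time at engagement levels 1-3 with rare excursions to 0 and 5-6,
# mimicking the heavy class imbalance of real sessions.  Dwell times are long
# relative to the 1-s feature window (aggregate ~0.2 level changes/s), a
# requirement of the separable-regime construction: if the engagement state
# flipped faster than the windowed features can settle, no classifier could
# recover it
DEFAULT_BEHAVIOR_TIMING = {
    "eye_gaze": (30.0, 12.0),
    "vocalization": (8.0, 30.0),
    "smiling": (10.0, 40.0),
    "self_initiated": (12.0, 60.0),
    "triadic": (10.0, 90.0),
    "imitation": (8.0, 120.0),
}

# arm-swing amplitude (rad) per engagement class 0..6; successive regimes
# differ by a factor 2 and the lowest regime still moves the wrist several
# pixels (well above the coordinate-noise floor), keeping every pair of
# regimes separated relative to noise
DEFAULT_SWING_AMPLITUDE = (0.05, 0.10, 0.20, 0.40, 0.80, 1.60, 3.20)
# swing frequency (Hz) per class: more engaged children move faster
DEFAULT_SWING_FREQ_HZ = (0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 1.7)
# facial keypoint motion scale (px) per class, same factor-2 ladder
DEFAULT_FACE_JITTER = (0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.6)


@dataclass
class SyntheticConfig:
    """Conditions the generator reproduces; defaults mirror the study scale."""

    n_subjects: int = 18
    n_td: int = 13  # remainder tagged ASD, matching the 13/5 cohort
    n_frames: int = 12_000  # ~ the middle of the per-subject datapoint range
    fps: float = 30.0
    swing_amplitude: tuple[float, ...] = DEFAULT_SWING_AMPLITUDE
    swing_freq_hz: tuple[float, ...] = DEFAULT_SWING_FREQ_HZ
    face_jitter: tuple[float, ...] = DEFAULT_FACE_JITTER
    behavior_timing: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR_TIMING))
    noise_sigma: float = 1.0  # px, iid coordinate noise on every keypoint
    drop_probability: float = 0.01  # upstream per-frame processing dropouts
    smile_lip_widen: float = 1.3  # lip x-spread factor while smiling is active
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not 0 < self.n_td <= self.n_subjects:
            raise ConfigError("need 1 <= n_td <= n_subjects")
        for name, seq in (
            ("swing_amplitude", self.swing_amplitude),
            ("swing_freq_hz", self.swing_freq_hz),
            ("face_jitter", self.face_jitter),
        ):
            if len(seq) != 7:
                raise ConfigError(f"{name} needs 7 per-class values")
        if any(b <= a for a, b in zip(self.swing_amplitude, self.swing_amplitude[1:])):
            raise ConfigError("swing_amplitude must be strictly increasing with class")

    def collapsed(self) -> "SyntheticConfig":
        """Same event process, but identical kinematics for every class.

        Removes all feature-label signal, the negative control for
        parameter-recovery checks.
        """
        mid = 3
        return replace(
            self,
            swing_amplitude=tuple(
                self.swing_amplitude[mid] + 1e-6 * k for k in range(7)
            ),
            swing_freq_hz=(self.swing_freq_hz[mid],) * 7,
            face_jitter=(self.face_jitter[mid],) * 7,
            smile_lip_widen=1.0,
        )


def sample_events(config: SyntheticConfig, rng: np.random.Generator) -> list[BehaviorEvent]:
    """Alternating-renewal event draw: Exp(off) gaps, Exp(on) durations."""
    duration = config.n_frames / config.fps
    events = []
    for b in BEHAVIORS:
        mean_on, mean_off = config.behavior_timing[b]
        if mean_on <= 0:
            continue
        t = rng.exponential(mean_off) if mean_off > 0 else 0.0
        while t < duration:
            on = max(rng.exponential(mean_on), 1.0 / config.fps)
            stop = min(t + on, duration)
            if stop > t:
                events.append(BehaviorEvent(b, t, stop))
            t = stop + max(rng.exponential(mean_off), 1.0 / config.fps)
    return merge_events(events)


# fixed torso layout in image pixels (origin top-left, y down)
_NECK = np.array([320.0, 200.0])
_MID_HIP = np.array([320.0, 330.0])
_SHOULDER_HALF = 45.0
_UPPER_ARM = 55.0
_FOREARM = 50.0
_FACE_CENTER = np.array([320.0, 150.0])


def _face_template() -> np.ndarray:
    """A stylized 70-point face: plausible eye/lip/pupil geometry in px."""
    pts = np.zeros((N_FACE, 2))
    # jaw/brow/nose points (0-35): coarse ellipse placeholders
    ang = np.linspace(-np.pi / 2, np.pi / 2, 17)
    pts[0:17, 0] = 40 * np.sin(ang)
    pts[0:17, 1] = 10 + 30 * np.cos(ang) * -1 + 40
    pts[17:27, 0] = np.linspace(-30, 30, 10)
    pts[17:27, 1] = -25.0
    pts[27:36, 0] = np.linspace(-8, 8, 9)
    pts[27:36, 1] = np.linspace(-15, 5, 9)
    # eyes 36-47: two 6-point contours
    for base, cx in ((36, -18.0), (42, 18.0)):
        t = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts[base : base + 6, 0] = cx + 7 * np.cos(t)
        pts[base : base + 6, 1] = -10 + 3 * np.sin(t)
    # lips 48-67: outer (12) and inner (8) contours
    t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    pts[48:60, 0] = 14 * np.cos(t)
    pts[48:60, 1] = 22 + 6 * np.sin(t)
    t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts[60:68, 0] = 9 * np.cos(t)
    pts[60:68, 1] = 22 + 3 * np.sin(t)
    # pupils 68-69
    pts[68] = (-18.0, -10.0)
    pts[69] = (18.0, -10.0)
    return pts + _FACE_CENTER


_FACE_BASE = _face_template()
_LIP_IDX = np.arange(48, 68)


def _arm_chain(shoulder, alpha, gamma, side):
    """Elbow/wrist positions from shoulder angle alpha and elbow bend gamma.

    alpha is measured from straight-down (y+); positive swings outward
    (side = +1 right of image for the left arm, -1 for the right).
    """
    d1 = np.stack([side * np.sin(alpha), np.cos(alpha)], axis=-1)
    elbow = shoulder + _UPPER_ARM * d1
    beta = alpha + gamma
    d2 = np.stack([side * np.sin(beta), np.cos(beta)], axis=-1)
    wrist = elbow + _FOREARM * d2
    return elbow, wrist


def generate_subject(
    config: SyntheticConfig, seed: int, subject_id: str = "synthetic"
) -> tuple[KeypointTrack, list[BehaviorEvent], EngagementSeries]:
    """One subject's keypoint track, its annotations, and the true labels.

    Joint-angle trajectories are sinusoids whose amplitude/frequency follow
    the per-frame engagement class; iid Gaussian pixel noise and random frame
    drops emulate estimator error and upstream processing loss.
    """
    rng = np.random.default_rng(seed)
    events = sample_events(config, rng)
    truth = engagement_series(events, config.n_frames, config.fps)
    k = truth.klass
    t = np.arange(config.n_frames) / config.fps

    amp = np.asarray(config.swing_amplitude)[k]
    freq = np.asarray(config.swing_freq_hz)[k]
    jit = np.asarray(config.face_jitter)[k]
    phase = np.cumsum(2 * np.pi * freq / config.fps)  # continuous through regime switches
    ph_l, ph_r, ph_el, ph_er = rng.uniform(0, 2 * np.pi, size=4)

    alpha_l = 0.35 + amp * np.sin(phase + ph_l)
    alpha_r = 0.35 + amp * np.sin(phase + ph_r)
    gamma_l = 0.6 + 0.8 * amp * np.sin(0.7 * phase + ph_el)
    gamma_r = 0.6 + 0.8 * amp * np.sin(0.7 * phase + ph_er)

    ls = _NECK + np.array([_SHOULDER_HALF, 5.0])
    rs = _NECK + np.array([-_SHOULDER_HALF, 5.0])
    le, lw = _arm_chain(ls, alpha_l, gamma_l, side=+1)
    re, rw = _arm_chain(rs, alpha_r, gamma_r, side=-1)

    body = np.zeros((config.n_frames, N_BODY, 3))
    body[:, :, 2] = 0.9
    body[:, NOSE, :2] = _FACE_CENTER
    body[:, NECK, :2] = _NECK
    body[:, MID_HIP, :2] = _MID_HIP
    body[:, L_SHOULDER, :2] = ls
    body[:, R_SHOULDER, :2] = rs
    body[:, L_ELBOW, :2] = le
    body[:, R_ELBOW, :2] = re
    body[:, L_WRIST, :2] = lw
    body[:, R_WRIST, :2] = rw

    face = np.zeros((config.n_frames, N_FACE, 3))
    face[:, :, 2] = 0.85
    face[:, :, :2] = _FACE_BASE
    smiling = np.zeros(config.n_frames, dtype=bool)
    for e in events:
        if e.behavior == "smiling":
            smiling |= (t >= e.start_s) & (t < e.stop_s)
    if config.smile_lip_widen != 1.0 and smiling.any():
        lips = face[np.ix_(smiling, _LIP_IDX)][:, :, 0]
        face[np.ix_(smiling, _LIP_IDX, [0])] = (
            _FACE_CENTER[0] + config.smile_lip_widen * (lips - _FACE_CENTER[0])
        )[:, :, None]
    # engagement-dependent facial motion: shared head sway + per-point jitter
    sway = jit[:, None] * np.stack(
        [np.sin(0.9 * phase + ph_l), np.cos(1.1 * phase + ph_r)], axis=-1
    )
    face[:, :, :2] += sway[:, None, :]
    face[:, :, :2] += rng.normal(0, 1, size=(config.n_frames, N_FACE, 2)) * jit[:, None, None]

    if config.noise_sigma > 0:
        body[:, :, :2] += rng.normal(0, config.noise_sigma, size=(config.n_frames, N_BODY, 2))
        face[:, :, :2] += rng.normal(0, config.noise_sigma, size=(config.n_frames, N_FACE, 2))

    keep = rng.random(config.n_frames) >= config.drop_probability
    keep[0] = True  # anchor the track start
    track = KeypointTrack(
        subject_id=subject_id,
        fps=config.fps,
        frame_index=np.flatnonzero(keep),
        body=body[keep],
        face=face[keep],
        gap_mask=np.zeros(int(keep.sum()), dtype=bool),
    )
    return track, events, truth


def generate_cohort(
    config: SyntheticConfig,
) -> list[tuple[KeypointTrack, list[BehaviorEvent], EngagementSeries, str]]:
    """Per-subject tracks with TD/ASD group tags; seeds derived from the master."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    out = []
    for i, s in enumerate(seeds):
        group = "TD" if i < config.n_td else "ASD"
        sid = f"S{i + 1:02d}"
        track, events, truth = generate_subject(config, int(s), subject_id=sid)
        out.append((track, events, truth, group))
    return out
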