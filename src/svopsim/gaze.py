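"""Gaze-stream analysis: fixation verification and seen/unseen classification.

The instrument replaces the response button with the eye itself: a
stimulus counts as perceived when the subject makes a saccade whose
vector (direction and amplitude from the fixation target) matches the
fixation-to-stimulus vector within tolerance.  A stimulus counts as not
perceived when the response window (1 s by default) elapses with gaze
held on the fixation target.  Anything else -- lost tracking, or a gaze
shift on a non-matching vector -- is invalid and decides nothing.

All tolerances are in degrees of visual angle, so screen positions are
converted to angles through the concurrently tracked eye pose rather
than compared in raw millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .projection import EyePose, angular_offset, angular_separation

__all__ = [
    "GazeSample",
    "GazeStream",
    "ResponseDecision",
    "TrackingLossError",
    "verify_fixation",
    "classify_response",
    "detect_saccade",
    "SACCADE_VELOCITY_THRESHOLD_DEG_S",
]

#: Inter-sample angular velocity above which a displacement is a saccade.
SACCADE_VELOCITY_THRESHOLD_DEG_S = 100.0


class TrackingLossError(RuntimeError):
    """More than half the samples in the evaluation window are invalid."""


@dataclass(frozen=True)
class GazeSample:
    t_ms: float
    x_mm: float
    y_mm: float
    eye_pose: EyePose
    valid: bool = True


@dataclass
class GazeStream:
    """Columnar gaze recording: time, screen intersection, eye pose, validity."""

    t_ms: np.ndarray
    xy_mm: np.ndarray
    eye_xyz_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.xy_mm = np.asarray(self.xy_mm, dtype=float)
        self.eye_xyz_mm = np.asarray(self.eye_xyz_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.shape[0]
        if self.xy_mm.shape != (n, 2) or self.eye_xyz_mm.shape != (n, 3):
            raise ValueError("inconsistent gaze stream column shapes")
        if self.valid.shape != (n,):
            raise ValueError("inconsistent gaze stream column shapes")
        if n > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("gaze samples must be strictly time-ordered")

    def __len__(self) -> int:
        return int(self.t_ms.shape[0])

    @classmethod
    def from_samples(cls, samples: Sequence[GazeSample]) -> "GazeStream":
        return cls(
            t_ms=np.array([s.t_ms for s in samples]),
            xy_mm=np.array([[s.x_mm, s.y_mm] for s in samples]),
            eye_xyz_mm=np.array([s.eye_pose.as_array() for s in samples]),
            valid=np.array([s.valid for s in samples]),
        )

    def slice_time(self, t0_ms: float, t1_ms: float) -> "GazeStream":
        m = (self.t_ms >= t0_ms) & (self.t_ms <= t1_ms)
        return GazeStream(self.t_ms[m], self.xy_mm[m], self.eye_xyz_mm[m], self.valid[m])

    def pose_at(self, i: int) -> EyePose:
        x, y, z = self.eye_xyz_mm[i]
        return EyePose(float(x), float(y), float(z))

    @property
    def final_pose(self) -> EyePose:
        return self.pose_at(len(self) - 1)


@dataclass(frozen=True)
class ResponseDecision:
    outcome: str  # "seen" | "unseen" | "invalid"
    saccade_latency_ms: float | None = None
    landing_xy_mm: tuple[float, float] | None = None


def _angles_to_target(stream: GazeStream, target_xy_mm, idx: np.ndarray) -> np.ndarray:
    """Angle (deg) between each selected gaze point and a screen target,
    subtended at that sample's eye position (vectorised)."""
    eyes = stream.eye_xyz_mm[idx]
    gaze3 = np.column_stack([stream.xy_mm[idx], np.zeros(len(idx))])
    targ3 = np.array([target_xy_mm[0], target_xy_mm[1], 0.0])
    u = gaze3 - eyes
    v = targ3[None, :] - eyes
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def verify_fixation(
    stream: GazeStream,
    target_xy_mm,
    tolerance_deg: float = 2.0,
    dwell_ms: float = 200.0,
    eye_pose: EyePose | None = None,
) -> bool:
    """True iff the most recent ``dwell_ms`` of valid samples all lie within
    ``tolerance_deg`` of the target.

    Raises :class:`TrackingLossError` when more than half the samples in
    the window are invalid (the presentation is withheld).
    """
    if tolerance_deg <= 0 or dwell_ms <= 0:
        raise ValueError("tolerance_deg and dwell_ms must be positive")
    if len(stream) == 0:
        raise TrackingLossError("empty gaze stream")
    t_end = stream.t_ms[-1]
    window = stream.t_ms >= t_end - dwell_ms
    n_window = int(window.sum())
    n_valid = int((window & stream.valid).sum())
    if n_valid < 0.5 * n_window or n_valid == 0:
        raise TrackingLossError(
            f"{n_window - n_valid}/{n_window} invalid samples in fixation window"
        )
    idx = np.flatnonzero(window & stream.valid)
    ang = _angles_to_target(stream, target_xy_mm, idx)
    return bool(np.all(ang <= tolerance_deg))


def detect_saccade(
    stream: GazeStream,
    velocity_threshold_deg_s: float = SACCADE_VELOCITY_THRESHOLD_DEG_S,
) -> tuple[float, np.ndarray] | None:
    """First suprathreshold-velocity displacement in the stream.

    Returns ``(onset_ms, landing_xy_mm)`` where onset is the time the
    displaced position is first observed and landing is the componentwise
    median of the steady samples after the movement, or ``None`` when no
    inter-sample velocity exceeds the threshold.
    """
    vi = np.flatnonzero(stream.valid)
    if vi.size < 2:
        return None
    t = stream.t_ms[vi]
    xy = stream.xy_mm[vi]
    eyes = stream.eye_xyz_mm[vi]
    gaze3 = np.column_stack([xy, np.zeros(vi.size)])
    d = gaze3 - eyes
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    step_deg = np.degrees(np.arccos(cosang))
    vel = step_deg / (np.diff(t) / 1000.0)
    fast = vel > velocity_threshold_deg_s
    if not np.any(fast):
        return None
    k = int(np.argmax(fast))  # first fast interval: samples k -> k+1
    onset_ms = float(t[k + 1])
    # movement ends at the first slow interval after k
    m = k + 1
    while m < len(vel) and fast[m]:
        m += 1
    steady = xy[m:] if m < len(xy) else xy[-1:]
    landing = np.median(steady, axis=0)
    return onset_ms, landing


def classify_response(
    stream: GazeStream,
    fixation_xy_mm,
    stimulus_xy_mm,
    onset_ms: float,
    window_ms: float = 1000.0,
    direction_tol_deg: float = 20.0,
    amplitude_tol_frac: float = 0.30,
    eye_pose: EyePose | None = None,
    fixation_tol_deg: float = 2.0,
    velocity_threshold_deg_s: float = SACCADE_VELOCITY_THRESHOLD_DEG_S,
) -> ResponseDecision:
    """Decide seen / unseen / invalid from the gaze stream.

    *seen*: a saccade beginning after stimulus onset lands, within the
    window, on a vector matching the fixation-to-stimulus vector in both
    direction (within ``direction_tol_deg``) and amplitude (within
    ``amplitude_tol_frac`` of the required amplitude).
    *unseen*: the window elapses with gaze held at fixation.
    *invalid*: tracking lost, or gaze left fixation on a non-matching vector.
    """
    sub = stream.slice_time(onset_ms, onset_ms + window_ms)
    if len(sub) == 0 or not np.any(sub.valid):
        return ResponseDecision("invalid")
    if int(sub.valid.sum()) < 0.5 * len(sub):
        return ResponseDecision("invalid")

    sac = detect_saccade(sub, velocity_threshold_deg_s)
    if sac is None:
        idx = np.flatnonzero(sub.valid)
        ang = _angles_to_target(sub, fixation_xy_mm, idx)
        if np.all(ang <= fixation_tol_deg):
            return ResponseDecision("unseen")
        return ResponseDecision("invalid")

    sac_onset_ms, landing = sac
    # evaluate both vectors through the eye pose at the saccade landing
    last_valid = int(np.flatnonzero(sub.valid)[-1])
    pose = eye_pose if eye_pose is not None else sub.pose_at(last_valid)
    required = angular_offset(stimulus_xy_mm, pose, fixation_xy_mm)
    actual = angular_offset(landing, pose, fixation_xy_mm)
    req_amp = float(np.hypot(*required))
    act_amp = float(np.hypot(*actual))
    if req_amp <= 0:
        return ResponseDecision("invalid")
    dir_diff = np.degrees(
        np.abs(
            np.angle(
                np.exp(
                    1j
                    * (np.arctan2(actual[1], actual[0]) - np.arctan2(required[1], required[0]))
                )
            )
        )
    )
    if dir_diff <= direction_tol_deg and abs(act_amp - req_amp) <= amplitude_tol_frac * req_amp:
        return ResponseDecision(
            "seen",
            saccade_latency_ms=float(sac_onset_ms - onset_ms),
            landing_xy_mm=(float(landing[0]), float(landing[1])),
        )
    return ResponseDecision("invalid")
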