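"""Gaze-contingent screen geometry and the calibrated display model.

The subject views a flat screen from a tracked 3-D eye position, so the
screen point that places a stimulus at a required angular offset from the
fixation target depends on where the eye currently is.  All geometry here
is exact trigonometry in a fixation-centred tangent frame: the forward
axis points from the eye to the fixation point, and a stimulus at offset
``(theta_x, theta_y)`` lies along ``forward + tan(theta_x)*right +
tan(theta_y)*up``.  Re-deriving the angular offset of the projected point
through the same frame returns the request exactly, for any eye pose --
that is the compensation contract the instrument relies on when the
subject's head moves.

The display is modelled by a monotone look-up table (LUT) pairing grey
levels with calibrated luminances; requests above the table's top entry
raise :class:`GamutError`, which is the physical reason the instrument
cannot show stimuli brighter than the 14 dB level.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import DB_FLOOR, db_to_increment

__all__ = [
    "ScreenModel",
    "EyePose",
    "OffScreenError",
    "GamutError",
    "project_stimulus",
    "project_size",
    "angular_offset",
    "angular_separation",
    "lut_grey_for_luminance",
    "default_lut",
]


class OffScreenError(ValueError):
    """Projected stimulus does not fall (fully) on the display."""


class GamutError(ValueError):
    """Requested luminance exceeds the display's calibrated maximum."""


@dataclass(frozen=True)
class EyePose:
    """Eye position relative to the screen centre (mm); +x right, +y up,
    z the perpendicular viewing distance (nominally ~550 mm)."""

    x_mm: float = 0.0
    y_mm: float = 0.0
    z_mm: float = 550.0

    def __post_init__(self) -> None:
        if self.z_mm <= 0:
            raise ValueError("viewing distance z_mm must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm, self.z_mm], dtype=float)


def default_lut(
    max_cdm2: float | None = None, n_grey: int = 1024, gamma: float = 2.2
) -> np.ndarray:
    """Synthetic gamma-curve LUT: (n_grey, 2) array of (grey, luminance).

    The top entry defaults to the brightest stimulus the test needs:
    the 14 dB increment plus the 10 cd/m^2 background.
    """
    if max_cdm2 is None:
        max_cdm2 = db_to_increment(DB_FLOOR) + 10.0
    grey = np.arange(n_grey, dtype=float)
    lum = max_cdm2 * (grey / (n_grey - 1)) ** gamma
    return np.column_stack([grey, lum])


@dataclass
class ScreenModel:
    """Physical display: 24-inch 16:10 panel by default, plus its LUT."""

    width_mm: float = 518.0
    height_mm: float = 324.0
    background_cdm2: float = 10.0
    lut: np.ndarray = dc_field(default_factory=default_lut)

    def __post_init__(self) -> None:
        self.lut = np.asarray(self.lut, dtype=float)
        if self.lut.ndim != 2 or self.lut.shape[1] != 2:
            raise ValueError("lut must be an (n, 2) array of (grey, luminance)")
        if np.any(np.diff(self.lut[:, 1]) <= 0):
            raise ValueError("lut luminances must be strictly increasing")

    @property
    def max_cdm2(self) -> float:
        return float(self.lut[-1, 1])

    def contains(self, xy_mm: np.ndarray | tuple[float, float], margin_mm: float = 0.0) -> bool:
        x, y = float(xy_mm[0]), float(xy_mm[1])
        return (
            abs(x) <= self.width_mm / 2.0 - margin_mm
            and abs(y) <= self.height_mm / 2.0 - margin_mm
        )


def _fixation_frame(eye: np.ndarray, fixation_xy_mm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (forward, right, up) of the fixation-centred frame."""
    fix3 = np.array([fixation_xy_mm[0], fixation_xy_mm[1], 0.0])
    fwd = fix3 - eye
    fwd = fwd / np.linalg.norm(fwd)
    up_world = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, up_world)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("degenerate geometry: gaze parallel to screen vertical")
    right = right / nr
    up = np.cross(right, fwd)
    return fwd, right, up


def project_stimulus(
    location_offset_deg: tuple[float, float],
    eye_pose: EyePose,
    fixation_screen_xy: tuple[float, float],
    screen: ScreenModel | None = None,
    margin_mm: float = 0.0,
) -> np.ndarray:
    """Screen point (mm) subtending the requested angular offset from fixation.

    Raises :class:`OffScreenError` when the point misses the screen (the
    caller treats the location as currently ineligible).
    """
    eye = eye_pose.as_array()
    fwd, right, up = _fixation_frame(eye, fixation_screen_xy)
    tx = np.tan(np.radians(location_offset_deg[0]))
    ty = np.tan(np.radians(location_offset_deg[1]))
    d = fwd + tx * right + ty * up
    if d[2] >= 0.0:  # ray does not travel toward the screen plane
        raise OffScreenError("stimulus direction misses the screen plane")
    t = -eye[2] / d[2]
    point = eye + t * d
    xy = point[:2]
    if screen is not None and not screen.contains(xy, margin_mm=margin_mm):
        raise OffScreenError(
            f"stimulus at ({xy[0]:.1f}, {xy[1]:.1f}) mm falls off-screen"
        )
    return xy


def angular_offset(
    screen_xy_mm,
    eye_pose: EyePose,
    fixation_screen_xy,
) -> np.ndarray:
    """Angular offset (deg, both components) of a screen point from fixation.

    Exact inverse of :func:`project_stimulus` for the same eye pose.
    """
    eye = eye_pose.as_array()
    fwd, right, up = _fixation_frame(eye, fixation_screen_xy)
    d = np.array([screen_xy_mm[0], screen_xy_mm[1], 0.0]) - eye
    df = d @ fwd
    if df <= 0:
        raise ValueError("screen point behind the eye")
    return np.degrees(np.arctan2([d @ right, d @ up], df))


def angular_separation(p_xy_mm, q_xy_mm, eye_pose: EyePose) -> float:
    """Angle (deg) subtended at the eye between two screen points."""
    eye = eye_pose.as_array()
    u = np.array([p_xy_mm[0], p_xy_mm[1], 0.0]) - eye
    v = np.array([q_xy_mm[0], q_xy_mm[1], 0.0]) - eye
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def project_size(diameter_deg: float, eye_pose: EyePose, screen_xy_mm) -> float:
    """On-screen diameter (mm) subtending ``diameter_deg`` at that point."""
    if diameter_deg < 0:
        raise ValueError("diameter must be non-negative")
    eye = eye_pose.as_array()
    d = np.array([screen_xy_mm[0], screen_xy_mm[1], 0.0]) - eye
    dist = float(np.linalg.norm(d))
    return 2.0 * dist * np.tan(np.radians(diameter_deg) / 2.0)


def lut_grey_for_luminance(screen_model: ScreenModel, luminance_cdm2: float) -> int:
    """Grey level whose calibrated luminance is nearest the request.

    Raises :class:`GamutError` for requests above the LUT's top entry.
    """
    lut = screen_model.lut
    lums = lut[:, 1]
    top = lums[-1]
    if luminance_cdm2 > top:
        raise GamutError(
            f"requested {luminance_cdm2:.2f} cd/m^2 exceeds display maximum "
            f"{top:.2f} cd/m^2"
        )
    i = int(np.searchsorted(lums, luminance_cdm2))
    if i == 0:
        return int(lut[0, 0])
    if i >= len(lums):
        return int(lut[-1, 0])
    below, above = lums[i - 1], lums[i]
    # ties break toward the lower grey level
    j = i - 1 if (luminance_cdm2 - below) <= (above - luminance_cdm2) else i
    return int(lut[j, 0])
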