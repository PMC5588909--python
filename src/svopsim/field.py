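"""Test-pattern geometry, the perimetric decibel scale, and visual-field containers.

Conventions
-----------
Coordinates are degrees of visual angle in a screen-direction frame:
``+x`` is the subject's right, ``+y`` superior.  For the right eye ``+x``
is therefore the temporal field; the left-eye pattern is the mirror image
(x negated), so the nasal 27-degree extension and the blind spot land on
the correct side of space for either eye.

The decibel scale is the standard-automated-perimetry attenuation scale:
``increment = L0 * 10**(-dB/10)`` with ``L0 = 10000 apostilb = 10000/pi
cd/m^2``.  Higher dB means a dimmer stimulus and better sensitivity.  The
stimulus as displayed adds this increment to the 10 cd/m^2 background, so
the brightest displayable level (14 dB) corresponds to a screen luminance
of about 136.7 cd/m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "L0_CDM2",
    "DB_FLOOR",
    "DB_CEILING",
    "FieldLocation",
    "TestPattern",
    "StimulusSpec",
    "VisualField",
    "generate_pattern",
    "db_to_increment",
    "increment_to_db",
    "truncate_for_comparison",
    "goldmann_diameter",
]

#: 0 dB reference increment: 10,000 apostilb expressed in cd/m^2.
L0_CDM2 = 10000.0 / math.pi

#: Displayable level range (dB) of the instrument.
DB_FLOOR = 14.0
DB_CEILING = 40.0

# Goldmann stimulus areas in mm^2 on the 300 mm bowl; each size quadruples area.
_GOLDMANN_AREA_MM2 = {"I": 0.25, "II": 1.0, "III": 4.0, "IV": 16.0, "V": 64.0}
_GOLDMANN_REFERENCE_MM = 300.0


class UnsupportedPatternError(ValueError):
    """Requested test pattern is not implemented."""


@dataclass(frozen=True)
class FieldLocation:
    """A single test point in visual-angle space.

    ``x_deg``/``y_deg`` follow the screen-direction convention above;
    ``is_blind_spot`` flags the temporal pair straddling the physiologic
    blind spot (zero true sensitivity).
    """

    x_deg: float
    y_deg: float
    eye: str
    is_blind_spot: bool = False

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x_deg, self.y_deg)


@dataclass(frozen=True)
class TestPattern:
    """An ordered grid of test locations for one eye."""

    locations: tuple[FieldLocation, ...]
    pattern_name: str
    eye: str

    def __post_init__(self) -> None:
        xy = [loc.xy for loc in self.locations]
        if len(set(xy)) != len(xy):
            raise ValueError("duplicate coordinates in test pattern")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    def index_of(self, x_deg: float, y_deg: float) -> int:
        for i, loc in enumerate(self.locations):
            if loc.x_deg == x_deg and loc.y_deg == y_deg:
                return i
        raise KeyError(f"({x_deg}, {y_deg}) not in pattern")

    @property
    def blind_spot_indices(self) -> tuple[int, ...]:
        return tuple(i for i, loc in enumerate(self.locations) if loc.is_blind_spot)

    @property
    def non_blind_spot_indices(self) -> tuple[int, ...]:
        return tuple(i for i, loc in enumerate(self.locations) if not loc.is_blind_spot)

    def neighbor_indices(self, i: int, spacing_deg: float = 6.0) -> tuple[int, ...]:
        """Indices of the 4-neighbors (one grid step along x or y)."""
        loc = self.locations[i]
        out = []
        for j, other in enumerate(self.locations):
            dx = abs(other.x_deg - loc.x_deg)
            dy = abs(other.y_deg - loc.y_deg)
            if (dx == spacing_deg and dy == 0.0) or (dx == 0.0 and dy == spacing_deg):
                out.append(j)
        return tuple(out)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (x_deg, y_deg)."""
        return np.array([loc.xy for loc in self.locations], dtype=float)


@dataclass(frozen=True)
class StimulusSpec:
    """Physical stimulus parameters: Goldmann III, 200 ms, on 10 cd/m^2."""

    level_db: float = 25.0
    diameter_deg: float = dc_field(default=0.0)
    duration_ms: float = 200.0
    background_cdm2: float = 10.0

    def __post_init__(self) -> None:
        if self.diameter_deg == 0.0:
            object.__setattr__(self, "diameter_deg", goldmann_diameter("III"))
        if not (DB_FLOOR <= self.level_db <= DB_CEILING):
            raise ValueError(
                f"level_db {self.level_db} outside displayable range "
                f"[{DB_FLOOR}, {DB_CEILING}]"
            )

    def luminance_cdm2(self) -> float:
        """Total on-screen stimulus luminance: increment plus background."""
        return db_to_increment(self.level_db) + self.background_cdm2


@dataclass
class VisualField:
    """Per-location threshold estimates (dB) with test metadata.

    ``thresholds_db`` is aligned with ``pattern.locations``; NaN marks an
    undetermined location.  ``complete`` is true iff no location is missing.
    """

    pattern: TestPattern
    thresholds_db: np.ndarray
    test_version: str
    n_presentations: np.ndarray | None = None
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if self.thresholds_db.shape != (len(self.pattern),):
            raise ValueError("thresholds must align with the pattern")
        present = self.thresholds_db[~np.isnan(self.thresholds_db)]
        if present.size and (present.min() < DB_FLOOR or present.max() > DB_CEILING):
            raise ValueError(
                f"thresholds outside [{DB_FLOOR}, {DB_CEILING}] dB"
            )
        if self.n_presentations is None:
            self.n_presentations = np.zeros(len(self.pattern), dtype=int)
        else:
            self.n_presentations = np.asarray(self.n_presentations, dtype=int)

    @property
    def eye(self) -> str:
        return self.pattern.eye

    @property
    def complete(self) -> bool:
        return not np.any(np.isnan(self.thresholds_db))


def generate_pattern(pattern_name: str, eye: str) -> TestPattern:
    """Build the standard 24-2 grid for one eye.

    6-degree spacing offset 3 degrees from both meridians, nasal edge
    extended to 27 degrees, 54 points total; the temporal pair at
    (15, +/-3) is flagged as the blind spot.
    """
    if pattern_name != "24-2":
        raise UnsupportedPatternError(f"unsupported pattern: {pattern_name!r}")
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")

    # Right-eye frame (temporal = +x); nasal extension at x = -27.
    half_rows = {
        21: [-9, -3, 3, 9],
        15: [-15, -9, -3, 3, 9, 15],
        9: [-21, -15, -9, -3, 3, 9, 15, 21],
        3: [-27, -21, -15, -9, -3, 3, 9, 15, 21],
    }
    mirror = -1.0 if eye == "left" else 1.0
    blind_x = 15.0 * mirror  # temporal 15 degrees
    locations = []
    for abs_y, xs in half_rows.items():
        for sign in (1, -1):
            y = float(sign * abs_y)
            for x in xs:
                xf = mirror * float(x)
                locations.append(
                    FieldLocation(
                        x_deg=xf,
                        y_deg=y,
                        eye=eye,
                        is_blind_spot=(xf == blind_x and abs_y == 3),
                    )
                )
    locations.sort(key=lambda loc: (-loc.y_deg, loc.x_deg))
    return TestPattern(tuple(locations), pattern_name, eye)


def db_to_increment(level_db: float) -> float:
    """Luminance increment (cd/m^2) above background for a dB level."""
    if level_db < 0:
        raise ValueError(f"level_db must be >= 0, got {level_db}")
    return L0_CDM2 * 10.0 ** (-level_db / 10.0)


def increment_to_db(increment_cdm2: float) -> float:
    """Inverse of :func:`db_to_increment`."""
    if increment_cdm2 <= 0:
        raise ValueError(f"increment must be > 0, got {increment_cdm2}")
    return -10.0 * math.log10(increment_cdm2 / L0_CDM2)


def truncate_for_comparison(
    thresholds: Iterable[float] | np.ndarray, floor_db: float = DB_FLOOR
) -> np.ndarray:
    """Clip values below ``floor_db`` up to the floor (NaN passes through).

    Sensitivities below the instrument's brightest displayable level cannot
    be distinguished by it, so the comparison device's values are raised to
    that floor before any agreement statistic.
    """
    arr = np.asarray(thresholds, dtype=float)
    return np.where(np.isnan(arr), arr, np.maximum(arr, floor_db))


def goldmann_diameter(size_label: str) -> float:
    """Angular diameter (degrees) of a Goldmann stimulus size (I..V)."""
    try:
        area = _GOLDMANN_AREA_MM2[size_label]
    except KeyError:
        raise ValueError(f"unknown Goldmann size {size_label!r}") from None
    radius_mm = math.sqrt(area / math.pi)
    return 2.0 * math.degrees(math.atan(radius_mm / _GOLDMANN_REFERENCE_MM))
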