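"""Synthetic patient and eye tracker.

An :class:`ObserverModel` bundles a ground-truth sensitivity field with a
frequency-of-seeing response model and an oculomotor/tracking noise
model, and can synthesise the 60 Hz gaze streams the instrument would
record.  With all noise parameters at zero the synthesised streams are
exact: the gaze classifier recovers the intended decision for every
presentation, which is what makes closed-loop engine tests meaningful.

Frequency of seeing follows the standard perimetric model, a cumulative
Gaussian in dB with false-positive and false-negative floors::

    p(seen) = fp + (1 - fp - fn) * Phi((t - level) / slope)

where ``t`` is the true sensitivity: levels brighter (numerically lower)
than threshold are likely to be seen.  Tracker noise is modelled as
temporally correlated (AR(1)) angular jitter so that its RMS magnitude,
not its sample-to-sample velocity, is the controlled quantity; white
jitter of realistic magnitude would masquerade as saccades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.stats import norm

from .field import TestPattern
from .gaze import GazeStream
from .projection import EyePose

__all__ = [
    "ObserverModel",
    "FieldArchetype",
    "make_normal_field",
    "make_glaucoma_field",
    "p_seen",
    "respond",
    "synthesize_gaze",
    "synthesize_fixation",
]

_SAMPLE_HZ = 60.0
_DT_MS = 1000.0 / _SAMPLE_HZ
#: lag-1 correlation of the tracker jitter process
_JITTER_RHO = 0.9


@dataclass
class ObserverModel:
    """Ground-truth sensitivities plus psychometric and oculomotor noise.

    ``true_field`` is aligned with ``pattern.locations`` (dB; blind-spot
    points at 0).  ``gaze_noise_deg`` is the RMS tracker/fixational error
    (manufacturer-class devices are below 0.5 degrees); ``landing_noise_deg``
    the saccade endpoint error; ``dropout_prob`` the per-sample probability
    of a lost tracker sample.
    """

    pattern: TestPattern
    true_field: np.ndarray
    psychometric_slope_db: float = 2.0
    fp_rate: float = 0.03
    fn_rate: float = 0.03
    saccade_latency_mean_ms: float = 250.0
    saccade_latency_sd_ms: float = 50.0
    landing_noise_deg: float = 0.5
    gaze_noise_deg: float = 0.5
    dropout_prob: float = 0.02
    head_drift_mm_per_s: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.true_field = np.asarray(self.true_field, dtype=float)
        if self.true_field.shape != (len(self.pattern),):
            raise ValueError("true_field must align with the pattern")
        for name in ("fp_rate", "fn_rate", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.psychometric_slope_db < 0:
            raise ValueError("psychometric_slope_db must be >= 0")
        self.reset_rng()

    def reset_rng(self) -> None:
        self.rng = np.random.default_rng(self.rng_seed)

    def noiseless(self) -> "ObserverModel":
        """Copy with every stochastic parameter at zero (step psychometric)."""
        return replace(
            self,
            psychometric_slope_db=0.0,
            fp_rate=0.0,
            fn_rate=0.0,
            saccade_latency_sd_ms=0.0,
            landing_noise_deg=0.0,
            gaze_noise_deg=0.0,
            dropout_prob=0.0,
            head_drift_mm_per_s=0.0,
        )


@dataclass(frozen=True)
class FieldArchetype:
    """Parametric description of a ground-truth field shape.

    kinds: ``normal`` (hill of vision only), ``early_glaucoma`` (shallow
    superior paracentral cluster), ``arcuate`` (Bjerrum-region defect in
    one hemifield), ``advanced`` (diffuse loss plus deep defects in both
    hemifields).
    """

    kind: str = "normal"
    peak_db: float = 31.5
    slope_db_per_deg: float = 0.08
    noise_sd_db: float = 1.0
    defect_depth_db: float = 12.0
    hemifield: str = "superior"

    _KINDS = ("normal", "early_glaucoma", "arcuate", "advanced")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.hemifield not in ("superior", "inferior"):
            raise ValueError("hemifield must be 'superior' or 'inferior'")


def make_normal_field(
    pattern: TestPattern,
    peak_db: float = 31.5,
    slope_db_per_deg: float = 0.08,
    noise_sd_db: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hill-of-vision sensitivities: peak minus an eccentricity slope plus
    between-location noise; blind-spot points at 0 dB."""
    rng = rng or np.random.default_rng()
    ecc = np.array([loc.eccentricity_deg for loc in pattern])
    sens = peak_db - slope_db_per_deg * ecc
    if noise_sd_db > 0:
        sens = sens + rng.normal(0.0, noise_sd_db, size=len(pattern))
    sens = np.clip(sens, 0.0, 40.0)
    sens[list(pattern.blind_spot_indices)] = 0.0
    return sens


def _bjerrum_mask(pattern: TestPattern, superior: bool) -> np.ndarray:
    """Arcuate (Bjerrum) region: mid-eccentricity arc in one hemifield."""
    coords = pattern.coordinates()
    ecc = np.hypot(coords[:, 0], coords[:, 1])
    hemi = coords[:, 1] > 0 if superior else coords[:, 1] < 0
    return hemi & (ecc > 6.0) & (ecc < 24.0)


def make_glaucoma_field(
    pattern: TestPattern,
    archetype: FieldArchetype,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Normal field with a superimposed localized glaucomatous depression."""
    rng = rng or np.random.default_rng()
    base = make_normal_field(
        pattern, archetype.peak_db, archetype.slope_db_per_deg, archetype.noise_sd_db, rng
    )
    coords = pattern.coordinates()
    ecc = np.hypot(coords[:, 0], coords[:, 1])
    superior = archetype.hemifield == "superior"
    depth = archetype.defect_depth_db

    if archetype.kind == "normal" or depth == 0.0:
        mask = np.zeros(len(pattern), dtype=bool)
        loss = base * 0.0
    elif archetype.kind == "early_glaucoma":
        # shallow paracentral cluster on the nasal side of one hemifield
        nasal_sign = -1.0 if pattern.eye == "right" else 1.0
        hemi = coords[:, 1] > 0 if superior else coords[:, 1] < 0
        mask = hemi & (np.sign(coords[:, 0]) == nasal_sign) & (ecc < 16.0)
        loss = np.where(mask, depth, 0.0)
    elif archetype.kind == "arcuate":
        mask = _bjerrum_mask(pattern, superior)
        loss = np.where(mask, depth, 0.0)
    else:  # advanced: diffuse loss plus deep arcuates in both hemifields
        mask = _bjerrum_mask(pattern, True) | _bjerrum_mask(pattern, False)
        loss = 10.0 + np.where(mask, depth + 3.0, 0.0)

    sens = np.clip(base - loss, 0.0, 40.0)
    sens[list(pattern.blind_spot_indices)] = 0.0
    return sens


def p_seen(true_db: float, level_db: float, slope_db: float, fp: float, fn: float) -> float:
    """Closed-form frequency-of-seeing probability."""
    if slope_db == 0.0:
        # step limit: the deterministic observer sees iff level <= threshold
        core = 1.0 if level_db <= true_db else 0.0
    else:
        core = norm.cdf((true_db - level_db) / slope_db)
    return fp + (1.0 - fp - fn) * core


def respond(
    observer: ObserverModel,
    location_index: int,
    level_db: float,
    rng: np.random.Generator | None = None,
) -> str:
    """Draw a seen/unseen response from the observer's psychometric model."""
    rng = rng if rng is not None else observer.rng
    p = p_seen(
        float(observer.true_field[location_index]),
        level_db,
        observer.psychometric_slope_db,
        observer.fp_rate,
        observer.fn_rate,
    )
    return "seen" if rng.random() < p else "unseen"


def _deg_to_mm(deg: np.ndarray | float, z_mm: float) -> np.ndarray | float:
    return z_mm * np.tan(np.radians(deg))


def _jitter(rng: np.random.Generator, n: int, sd_deg: float, z_mm: float) -> np.ndarray:
    """AR(1) tracker jitter in screen mm, stationary RMS = sd_deg per axis."""
    if sd_deg == 0.0:
        return np.zeros((n, 2))
    eps = rng.normal(0.0, sd_deg, size=(n, 2))
    out = np.empty((n, 2))
    out[0] = eps[0]
    c = math.sqrt(1.0 - _JITTER_RHO**2)
    for i in range(1, n):
        out[i] = _JITTER_RHO * out[i - 1] + c * eps[i]
    return _deg_to_mm(out, z_mm)


def _poses(
    rng: np.random.Generator, n: int, start: EyePose, drift_mm_per_s: float
) -> np.ndarray:
    eyes = np.tile(start.as_array(), (n, 1))
    if drift_mm_per_s > 0 and n > 1:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = drift_mm_per_s * _DT_MS / 1000.0
        t = np.arange(n)[:, None]
        eyes[:, :2] += t * step * np.array([math.cos(theta), math.sin(theta)])
    return eyes


def synthesize_fixation(
    observer: ObserverModel,
    fixation_xy_mm,
    dwell_ms: float,
    eye_pose: EyePose,
    rng: np.random.Generator | None = None,
    t0_ms: float = 0.0,
) -> GazeStream:
    """Gaze stream of the subject holding the fixation target for ``dwell_ms``."""
    rng = rng if rng is not None else observer.rng
    n = max(2, int(round(dwell_ms / _DT_MS)) + 1)
    t = t0_ms + np.arange(n) * _DT_MS
    eyes = _poses(rng, n, eye_pose, observer.head_drift_mm_per_s)
    xy = np.tile(np.asarray(fixation_xy_mm, dtype=float), (n, 1))
    xy += _jitter(rng, n, observer.gaze_noise_deg, eye_pose.z_mm)
    valid = rng.random(n) >= observer.dropout_prob
    return GazeStream(t, xy, eyes, valid)


def synthesize_gaze(
    observer: ObserverModel,
    decision: str,
    fixation_xy_mm,
    stimulus_xy_mm,
    window_ms: float = 1000.0,
    eye_pose: EyePose = EyePose(),
    rng: np.random.Generator | None = None,
    t0_ms: float = 0.0,
) -> GazeStream:
    """Gaze stream over the response window realising an intended decision.

    ``decision = "seen"`` injects a saccade at a sampled latency landing on
    the stimulus plus endpoint noise; ``"unseen"`` holds fixation for the
    whole window.  Samples drop out with ``dropout_prob``.
    """
    if decision not in ("seen", "unseen"):
        raise ValueError(f"decision must be 'seen' or 'unseen', got {decision!r}")
    rng = rng if rng is not None else observer.rng
    n = int(round(window_ms / _DT_MS)) + 1
    t = t0_ms + np.arange(n) * _DT_MS
    eyes = _poses(rng, n, eye_pose, observer.head_drift_mm_per_s)
    fix = np.asarray(fixation_xy_mm, dtype=float)
    stim = np.asarray(stimulus_xy_mm, dtype=float)
    xy = np.tile(fix, (n, 1))
    if decision == "seen":
        latency = rng.normal(observer.saccade_latency_mean_ms, observer.saccade_latency_sd_ms)
        latency = float(np.clip(latency, 2.0 * _DT_MS, window_ms - 100.0))
        landing = stim + _deg_to_mm(
            rng.normal(0.0, observer.landing_noise_deg, size=2)
            if observer.landing_noise_deg > 0
            else np.zeros(2),
            eye_pose.z_mm,
        )
        moved = (t - t0_ms) >= latency
        xy[moved] = landing
    xy += _jitter(rng, n, observer.gaze_noise_deg, eye_pose.z_mm)
    valid = rng.random(n) >= observer.dropout_prob
    return GazeStream(t, xy, eyes, valid)
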