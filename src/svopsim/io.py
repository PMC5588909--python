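"""File formats: YAML configs and observers, CSV visual fields and LUTs,
JSONL gaze streams and event logs, and the run manifest.

Visual fields are plain CSV with ``# key: value`` header comments carrying
the test metadata, so a field file round-trips losslessly and stays
readable in any spreadsheet tool.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SessionConfig, SessionResult
from .field import (
    DB_CEILING,
    DB_FLOOR,
    FieldLocation,
    StimulusSpec,
    TestPattern,
    VisualField,
    generate_pattern,
)
from .gaze import GazeStream
from .observer import FieldArchetype, ObserverModel, make_glaucoma_field, make_normal_field
from .projection import ScreenModel, default_lut

__all__ = [
    "ConfigError",
    "FieldFormatError",
    "load_config",
    "save_config",
    "read_field",
    "write_field",
    "load_observer",
    "save_observer",
    "read_lut",
    "write_gaze_jsonl",
    "read_gaze_jsonl",
    "write_events_jsonl",
    "write_manifest",
]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class FieldFormatError(ValueError):
    """Visual-field file violates the format contract."""


_CONFIG_KEYS = {
    "version", "pattern_name", "eye", "fixation_tolerance_deg",
    "fixation_dwell_ms", "direction_tol_deg", "amplitude_tol_frac",
    "unseen_window_ms", "seed_start_db", "rng_seed", "retry_budget",
    "priority_weight", "stimulus", "screen",
}
_STIMULUS_KEYS = {"level_db", "diameter_deg", "duration_ms", "background_cdm2"}
_SCREEN_KEYS = {"width_mm", "height_mm", "background_cdm2", "lut_path"}


def load_config(path: str | Path) -> SessionConfig:
    """Load and validate a session config; defaults fill missing keys,
    unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    stim = kwargs.pop("stimulus", None)
    scr = kwargs.pop("screen", None)
    if stim is not None:
        bad = set(stim) - _STIMULUS_KEYS
        if bad:
            raise ConfigError(f"unknown stimulus keys: {sorted(bad)}")
        kwargs["stimulus"] = StimulusSpec(**stim)
    if scr is not None:
        bad = set(scr) - _SCREEN_KEYS
        if bad:
            raise ConfigError(f"unknown screen keys: {sorted(bad)}")
        scr = dict(scr)
        lut_path = scr.pop("lut_path", None)
        if lut_path is not None:
            scr["lut"] = read_lut(lut_path)
        kwargs["screen"] = ScreenModel(**scr)
    try:
        return SessionConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: SessionConfig, path: str | Path) -> None:
    raw = {
        "version": config.version,
        "pattern_name": config.pattern_name,
        "eye": config.eye,
        "fixation_tolerance_deg": config.fixation_tolerance_deg,
        "fixation_dwell_ms": config.fixation_dwell_ms,
        "direction_tol_deg": config.direction_tol_deg,
        "amplitude_tol_frac": config.amplitude_tol_frac,
        "unseen_window_ms": config.unseen_window_ms,
        "seed_start_db": config.seed_start_db,
        "rng_seed": config.rng_seed,
        "retry_budget": config.retry_budget,
        "priority_weight": config.priority_weight,
        "stimulus": {
            "level_db": config.stimulus.level_db,
            "diameter_deg": config.stimulus.diameter_deg,
            "duration_ms": config.stimulus.duration_ms,
            "background_cdm2": config.stimulus.background_cdm2,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_field(field: VisualField, path: str | Path) -> None:
    """CSV with metadata comment header; one row per location."""
    coords = field.pattern.coordinates()
    df = pd.DataFrame({
        "x_deg": coords[:, 0],
        "y_deg": coords[:, 1],
        "threshold_db": field.thresholds_db,
        "n_presentations": field.n_presentations,
        "is_blind_spot": [int(loc.is_blind_spot) for loc in field.pattern],
    })
    header = (
        f"# eye: {field.eye}\n"
        f"# pattern: {field.pattern.pattern_name}\n"
        f"# version: {field.test_version}\n"
        f"# complete: {field.complete}\n"
        f"# duration_s: {field.duration_s:.3f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g")


def read_field(path: str | Path) -> VisualField:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    required = {"x_deg", "y_deg", "threshold_db", "n_presentations", "is_blind_spot"}
    if not required <= set(df.columns):
        raise FieldFormatError(f"missing columns: {sorted(required - set(df.columns))}")
    for key in ("eye", "pattern", "version"):
        if key not in meta:
            raise FieldFormatError(f"missing metadata comment: {key}")
    pattern = generate_pattern(meta["pattern"], meta["eye"])
    if len(df) != len(pattern):
        raise FieldFormatError(
            f"expected {len(pattern)} rows for pattern {meta['pattern']}, got {len(df)}"
        )
    thr = np.full(len(pattern), np.nan)
    npres = np.zeros(len(pattern), dtype=int)
    for _, row in df.iterrows():
        i = pattern.index_of(float(row.x_deg), float(row.y_deg))
        thr[i] = row.threshold_db
        npres[i] = row.n_presentations
    present = thr[~np.isnan(thr)]
    if present.size and (present.min() < DB_FLOOR or present.max() > DB_CEILING):
        raise FieldFormatError(
            f"threshold outside [{DB_FLOOR}, {DB_CEILING}] dB in {path}"
        )
    return VisualField(
        pattern=pattern,
        thresholds_db=thr,
        test_version=meta["version"],
        n_presentations=npres,
        duration_s=float(meta.get("duration_s", 0.0)),
    )


_OBSERVER_KEYS = {
    "pattern_name", "eye", "archetype", "true_field",
    "psychometric_slope_db", "fp_rate", "fn_rate",
    "saccade_latency_mean_ms", "saccade_latency_sd_ms",
    "landing_noise_deg", "gaze_noise_deg", "dropout_prob",
    "head_drift_mm_per_s", "rng_seed",
}
_ARCHETYPE_KEYS = {"kind", "peak_db", "slope_db_per_deg", "noise_sd_db",
                   "defect_depth_db", "hemifield"}


def load_observer(path: str | Path) -> ObserverModel:
    """Observer YAML: noise parameters plus either an explicit ``true_field``
    list (pattern order) or an ``archetype`` block to generate one."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _OBSERVER_KEYS
    if unknown:
        raise ConfigError(f"unknown observer keys: {sorted(unknown)}")
    pattern = generate_pattern(raw.pop("pattern_name", "24-2"), raw.pop("eye", "right"))
    arch = raw.pop("archetype", None)
    tf = raw.pop("true_field", None)
    rng_seed = int(raw.get("rng_seed", 0))
    if tf is not None:
        true_field = np.asarray(tf, dtype=float)
    elif arch is not None:
        bad = set(arch) - _ARCHETYPE_KEYS
        if bad:
            raise ConfigError(f"unknown archetype keys: {sorted(bad)}")
        archetype = FieldArchetype(**arch)
        rng = np.random.default_rng(rng_seed)
        if archetype.kind == "normal":
            true_field = make_normal_field(
                pattern, archetype.peak_db, archetype.slope_db_per_deg,
                archetype.noise_sd_db, rng,
            )
        else:
            true_field = make_glaucoma_field(pattern, archetype, rng)
    else:
        raise ConfigError("observer needs either 'true_field' or 'archetype'")
    try:
        return ObserverModel(pattern=pattern, true_field=true_field, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_observer(observer: ObserverModel, path: str | Path) -> None:
    raw = {
        "pattern_name": observer.pattern.pattern_name,
        "eye": observer.pattern.eye,
        "true_field": [float(v) for v in observer.true_field],
        "psychometric_slope_db": observer.psychometric_slope_db,
        "fp_rate": observer.fp_rate,
        "fn_rate": observer.fn_rate,
        "saccade_latency_mean_ms": observer.saccade_latency_mean_ms,
        "saccade_latency_sd_ms": observer.saccade_latency_sd_ms,
        "landing_noise_deg": observer.landing_noise_deg,
        "gaze_noise_deg": observer.gaze_noise_deg,
        "dropout_prob": observer.dropout_prob,
        "head_drift_mm_per_s": observer.head_drift_mm_per_s,
        "rng_seed": observer.rng_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_lut(path: str | Path) -> np.ndarray:
    """Two-column CSV (grey_level, luminance_cdm2), strictly increasing."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ConfigError("LUT file must have exactly two columns")
    return df.to_numpy(dtype=float)


def write_gaze_jsonl(stream: GazeStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(stream)):
            rec = {
                "t_ms": float(stream.t_ms[i]),
                "x_mm": float(stream.xy_mm[i, 0]),
                "y_mm": float(stream.xy_mm[i, 1]),
                "eye_x_mm": float(stream.eye_xyz_mm[i, 0]),
                "eye_y_mm": float(stream.eye_xyz_mm[i, 1]),
                "eye_z_mm": float(stream.eye_xyz_mm[i, 2]),
                "valid": bool(stream.valid[i]),
            }
            fh.write(json.dumps(rec) + "\n")


def read_gaze_jsonl(path: str | Path) -> GazeStream:
    t, xy, eyes, valid = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            t.append(rec["t_ms"])
            xy.append([rec["x_mm"], rec["y_mm"]])
            eyes.append([rec["eye_x_mm"], rec["eye_y_mm"], rec["eye_z_mm"]])
            valid.append(rec["valid"])
    return GazeStream(np.array(t), np.array(xy), np.array(eyes), np.array(valid))


def write_events_jsonl(result: SessionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev) + "\n")


def write_manifest(path: str | Path, seed: int, inputs: dict, outputs: list[str]) -> None:
    """Record everything needed to re-run a CLI invocation bit-identically."""
    manifest = {
        "tool": "svopsim",
        "tool_version": __version__,
        "seed": seed,
        "inputs": inputs,
        "outputs": sorted(str(o) for o in outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
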