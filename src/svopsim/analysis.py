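"""Agreement and repeatability statistics for simulated test results.

Mirrors the clinical analysis pipeline: exclusion bookkeeping (incomplete
gaze tests; button tests with a false-positive rate above 15%), 14 dB
truncation of the comparison device before any correlation, per-test
mean-sensitivity agreement, per-location Pearson correlation maps across
test pairs, and same-device test-retest repeatability over the 54 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SessionConfig, SessionResult, run_sap_like_session, run_session
from .field import DB_FLOOR, TestPattern, VisualField, generate_pattern, truncate_for_comparison
from .observer import FieldArchetype, ObserverModel, make_glaucoma_field, make_normal_field

__all__ = [
    "ComparisonPair",
    "PointwiseReport",
    "CohortSpec",
    "CohortReports",
    "apply_exclusions",
    "mean_sensitivity",
    "pointwise_correlation",
    "repeatability",
    "cohort_experiment",
    "FP_EXCLUSION_RATE",
]

#: Button-test reliability cutoff: exclude above 15% false positives.
FP_EXCLUSION_RATE = 0.15


@dataclass
class ComparisonPair:
    """Two fields from the same eye: cross-device or same-device repeat."""

    field_a: VisualField
    field_b: VisualField
    subject_id: str
    pair_kind: str = "cross_device"  # or "repeat"

    def __post_init__(self) -> None:
        if self.field_a.eye != self.field_b.eye:
            raise ValueError("paired fields must come from the same eye")
        if len(self.field_a.pattern) != len(self.field_b.pattern):
            raise ValueError("paired fields must use the same pattern")
        if self.pair_kind not in ("cross_device", "repeat"):
            raise ValueError(f"unknown pair_kind {self.pair_kind!r}")


@dataclass
class PointwiseReport:
    """Per-location Pearson r across pairs, plus headline summaries."""

    pattern: TestPattern
    r: np.ndarray
    n_pairs: int
    truncation_floor_db: float | None
    exclude_blind_spot: bool

    def _included(self) -> np.ndarray:
        r = self.r
        if self.exclude_blind_spot:
            r = r[list(self.pattern.non_blind_spot_indices)]
        return r[~np.isnan(r)]

    def summary(self) -> dict:
        r = self._included()
        return {
            "n_locations": int(r.size),
            "n_pairs": int(self.n_pairs),
            "mean_r": float(np.mean(r)) if r.size else float("nan"),
            "min_r": float(np.min(r)) if r.size else float("nan"),
            "max_r": float(np.max(r)) if r.size else float("nan"),
            "n_above_0.70": int(np.sum(r > 0.70)),
            "n_above_0.80": int(np.sum(r > 0.80)),
            "exclude_blind_spot": self.exclude_blind_spot,
        }

    def to_frame(self) -> pd.DataFrame:
        coords = self.pattern.coordinates()
        return pd.DataFrame({
            "x_deg": coords[:, 0],
            "y_deg": coords[:, 1],
            "r": self.r,
            "n": self.n_pairs,
            "is_blind_spot": [loc.is_blind_spot for loc in self.pattern],
        })


def apply_exclusions(results: list[SessionResult]) -> tuple[list[SessionResult], list[tuple[SessionResult, str]]]:
    """Split results into kept and (result, reason) excluded.

    Gaze tests are excluded iff incomplete; button tests iff their
    false-positive rate exceeds 15%.  Every exclusion carries exactly one
    reason; kept + excluded partition the input.
    """
    kept, excluded = [], []
    for res in results:
        if res.test_version == "sap_sim":
            if res.fp_rate is not None and res.fp_rate > FP_EXCLUSION_RATE:
                excluded.append((res, "false positives > 15%"))
            else:
                kept.append(res)
        else:
            if not res.complete:
                excluded.append((res, "incomplete test"))
            else:
                kept.append(res)
    return kept, excluded


def mean_sensitivity(field: VisualField, exclude_blind_spot: bool = True) -> float:
    """Arithmetic mean threshold (dB) over included locations."""
    thr = field.thresholds_db
    if exclude_blind_spot:
        thr = thr[list(field.pattern.non_blind_spot_indices)]
    return float(np.nanmean(thr))


def _pointwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r of two (n_pairs, n_locations) matrices."""
    n_loc = a.shape[1]
    out = np.full(n_loc, np.nan)
    for j in range(n_loc):
        x, y = a[:, j], b[:, j]
        m = ~(np.isnan(x) | np.isnan(y))
        if m.sum() < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
            continue
        out[j] = stats.pearsonr(x[m], y[m]).statistic
    return out


def pointwise_correlation(
    pairs: list[ComparisonPair],
    truncation_floor: float | None = DB_FLOOR,
    exclude_blind_spot: bool = True,
) -> PointwiseReport:
    """Per-location Pearson r of field_a vs field_b across pairs.

    ``field_b`` (the comparison device) is truncated at the floor *before*
    correlating; ``field_a`` is produced by an instrument that cannot go
    below the floor, so it is left untouched.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a pointwise correlation")
    pattern = pairs[0].field_a.pattern
    a = np.vstack([p.field_a.thresholds_db for p in pairs])
    b = np.vstack([p.field_b.thresholds_db for p in pairs])
    if truncation_floor is not None:
        b = truncate_for_comparison(b, truncation_floor)
    return PointwiseReport(
        pattern=pattern,
        r=_pointwise_r(a, b),
        n_pairs=len(pairs),
        truncation_floor_db=truncation_floor,
        exclude_blind_spot=exclude_blind_spot,
    )


def repeatability(
    repeat_pairs: list[ComparisonPair], exclude_blind_spot: bool = True
) -> PointwiseReport:
    """Test-retest pointwise correlation over same-device repeat pairs.

    No truncation is applied: both sides come from the same device and
    share its floor.  The headline repeatability figure is the summary's
    mean r over included locations.
    """
    for p in repeat_pairs:
        if p.pair_kind != "repeat":
            raise ValueError("repeatability expects same-device repeat pairs")
    return pointwise_correlation(
        repeat_pairs, truncation_floor=None, exclude_blind_spot=exclude_blind_spot
    )


@dataclass
class CohortSpec:
    """Synthetic cohort: counts, archetype mix, and observer noise levels."""

    n_healthy: int = 15
    n_glaucoma: int = 15
    archetype_mix: tuple[str, ...] = ("early_glaucoma", "arcuate", "advanced")
    repeat_fraction: float = 1.0
    master_seed: int = 0
    observer_overrides: dict = dc_field(default_factory=dict)
    glaucoma_dropout_prob: float | None = None


@dataclass
class CohortReports:
    """Bundle of the end-to-end simulated-study outputs."""

    mean_thresholds: pd.DataFrame
    mean_threshold_r: float
    mean_threshold_r_vs_truth: float
    pointwise: PointwiseReport
    svop_repeatability: PointwiseReport | None
    sap_repeatability: PointwiseReport | None
    n_excluded: int
    exclusion_reasons: list[str]
    durations_s: pd.DataFrame


def _build_cohort(spec: CohortSpec, pattern: TestPattern) -> list[ObserverModel]:
    ss = np.random.SeedSequence(spec.master_seed)
    observers = []
    field_rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = [int(s) for s in field_rng.integers(0, 2**31 - 1, size=spec.n_healthy + spec.n_glaucoma)]
    for k in range(spec.n_healthy):
        tf = make_normal_field(pattern, rng=np.random.default_rng(seeds[k]))
        observers.append(
            ObserverModel(pattern=pattern, true_field=tf, rng_seed=seeds[k],
                          **spec.observer_overrides)
        )
    for k in range(spec.n_glaucoma):
        seed = seeds[spec.n_healthy + k]
        kind = spec.archetype_mix[k % len(spec.archetype_mix)]
        arch = FieldArchetype(kind=kind, hemifield="superior" if k % 2 == 0 else "inferior")
        tf = make_glaucoma_field(pattern, arch, rng=np.random.default_rng(seed))
        overrides = dict(spec.observer_overrides)
        if spec.glaucoma_dropout_prob is not None:
            overrides["dropout_prob"] = spec.glaucoma_dropout_prob
        observers.append(
            ObserverModel(pattern=pattern, true_field=tf, rng_seed=seed, **overrides)
        )
    return observers


def cohort_experiment(
    spec: CohortSpec,
    config: SessionConfig | None = None,
    exclude_blind_spot: bool = True,
) -> CohortReports:
    """Simulate a cohort end-to-end and compute the study-style reports.

    Each observer is tested once per device for the agreement analysis;
    a ``repeat_fraction`` subset is tested twice per device for the
    repeatability analysis.  Exclusions are applied before pairing.
    """
    config = config or SessionConfig()
    pattern = generate_pattern(config.pattern_name, config.eye)
    observers = _build_cohort(spec, pattern)
    n_repeat = int(round(spec.repeat_fraction * len(observers)))

    rows, cross_pairs, svop_rep, sap_rep = [], [], [], []
    durations = []
    n_excluded = 0
    reasons: list[str] = []
    for k, obs in enumerate(observers):
        repeat = k < n_repeat
        svop_runs, sap_runs = [], []
        for r in range(2 if repeat else 1):
            cfg = replace(config, rng_seed=int(np.random.SeedSequence([spec.master_seed, k, r]).generate_state(1)[0] % (2**31)))
            svop_runs.append(run_session(cfg, obs))
            sap_runs.append(run_sap_like_session(cfg, obs))
        kept, excl = apply_exclusions(svop_runs + sap_runs)
        n_excluded += len(excl)
        reasons.extend(reason for _, reason in excl)
        kept_svop = [x for x in kept if x.test_version != "sap_sim"]
        kept_sap = [x for x in kept if x.test_version == "sap_sim"]
        for res in svop_runs + sap_runs:
            durations.append({"subject": k, "device": res.test_version,
                              "duration_s": res.duration_s, "complete": res.complete})
        if kept_svop and kept_sap:
            sv, sa = kept_svop[0], kept_sap[0]
            cross_pairs.append(
                ComparisonPair(sv.field, sa.field, subject_id=str(k))
            )
            rows.append({
                "subject": k,
                "svop_mean_db": mean_sensitivity(sv.field, exclude_blind_spot),
                "sap_mean_db": mean_sensitivity(sa.field, exclude_blind_spot),
                "truth_mean_db": float(np.mean(
                    np.maximum(obs.true_field, DB_FLOOR)[
                        list(pattern.non_blind_spot_indices) if exclude_blind_spot else slice(None)
                    ]
                )),
            })
        if len(kept_svop) == 2:
            svop_rep.append(
                ComparisonPair(kept_svop[0].field, kept_svop[1].field, str(k), "repeat")
            )
        if len(kept_sap) == 2:
            sap_rep.append(
                ComparisonPair(kept_sap[0].field, kept_sap[1].field, str(k), "repeat")
            )

    mean_df = pd.DataFrame(rows)
    r_cross = float(stats.pearsonr(mean_df.svop_mean_db, mean_df.sap_mean_db).statistic) if len(mean_df) >= 3 else float("nan")
    r_truth = float(stats.pearsonr(mean_df.svop_mean_db, mean_df.truth_mean_db).statistic) if len(mean_df) >= 3 else float("nan")
    pw = pointwise_correlation(cross_pairs, exclude_blind_spot=exclude_blind_spot) if len(cross_pairs) >= 3 else None
    return CohortReports(
        mean_thresholds=mean_df,
        mean_threshold_r=r_cross,
        mean_threshold_r_vs_truth=r_truth,
        pointwise=pw,
        svop_repeatability=repeatability(svop_rep, exclude_blind_spot) if len(svop_rep) >= 3 else None,
        sap_repeatability=repeatability(sap_rep, exclude_blind_spot) if len(sap_rep) >= 3 else None,
        n_excluded=n_excluded,
        exclusion_reasons=reasons,
        durations_s=pd.DataFrame(durations),
    )
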