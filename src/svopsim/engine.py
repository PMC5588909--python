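"""Threshold test engine: 4-2 bracketing, growth-pattern seeding, and the
fixation-gated gaze-contingent session loop.

Each location runs a classic full-threshold 4-2 staircase: steps of 4 dB
until the first response reversal, then 2 dB, terminating at the second
reversal with the threshold taken as the last level at which the
stimulus was seen.  Two consecutive unseen responses at the 14 dB floor
terminate as unmeasurable (recorded at the floor); two consecutive seen
responses at the 40 dB ceiling terminate at the ceiling.

Testing begins at four seed locations (one per quadrant); completed
thresholds propagate outward as starting levels (rounded mean of the
finished 4-neighbours).  Software v2 differs from v1 only in: starting
levels clamped to >= 18 dB (so no threshold rests on a single response),
a longer fixation dwell, and a scheduling priority that favours
locations stuck in the queue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .field import (
    DB_CEILING,
    DB_FLOOR,
    FieldLocation,
    StimulusSpec,
    TestPattern,
    VisualField,
    db_to_increment,
    generate_pattern,
)
from .gaze import TrackingLossError, classify_response, verify_fixation
from .observer import ObserverModel, respond, synthesize_fixation, synthesize_gaze
from .projection import (
    EyePose,
    OffScreenError,
    ScreenModel,
    project_size,
    project_stimulus,
)

__all__ = [
    "StaircaseState",
    "SessionConfig",
    "SessionResult",
    "StaircaseError",
    "SchedulingError",
    "seed_locations",
    "starting_level",
    "staircase_update",
    "eligible_locations",
    "run_session",
    "run_sap_like_session",
]

SEED_COORDS = ((9.0, 9.0), (9.0, -9.0), (-9.0, 9.0), (-9.0, -9.0))

_VERSION_DWELL_MS = {"v1": 200.0, "v2": 500.0}
_VERSION_PRIORITY = {"v1": 0.0, "v2": 0.05}


class StaircaseError(RuntimeError):
    """Invalid staircase transition (e.g. update after termination)."""


class SchedulingError(RuntimeError):
    """A location was scheduled before any neighbour finished."""


@dataclass
class StaircaseState:
    """Per-location 4-2 bracketing state."""

    location: FieldLocation
    index: int
    is_seed: bool = False
    current_level_db: int = 25
    last_response: str | None = None
    n_reversals: int = 0
    n_presentations: int = 0
    threshold_db: float | None = None
    started: bool = False
    finished: bool = False
    unmeasurable: bool = False
    _last_seen_level: int | None = None
    _floor_unseen_streak: int = 0
    _ceiling_seen_streak: int = 0


@dataclass
class SessionConfig:
    """Everything that defines one test run (see module docstring for the
    v1/v2 behavioural differences)."""

    version: str = "v2"
    pattern_name: str = "24-2"
    eye: str = "right"
    stimulus: StimulusSpec = dc_field(default_factory=StimulusSpec)
    fixation_tolerance_deg: float = 2.0
    fixation_tolerance_fn: Callable[[float], float] | None = None
    fixation_dwell_ms: float | None = None
    direction_tol_deg: float = 20.0
    amplitude_tol_frac: float = 0.30
    unseen_window_ms: float = 1000.0
    seed_start_db: int = 25
    rng_seed: int = 0
    retry_budget: int = 25
    priority_weight: float | None = None
    screen: ScreenModel = dc_field(default_factory=ScreenModel)

    def __post_init__(self) -> None:
        if self.version not in ("v1", "v2"):
            raise ValueError(f"version must be 'v1' or 'v2', got {self.version!r}")

    @property
    def dwell_ms(self) -> float:
        return self.fixation_dwell_ms if self.fixation_dwell_ms is not None else _VERSION_DWELL_MS[self.version]

    @property
    def scheduling_priority_weight(self) -> float:
        return self.priority_weight if self.priority_weight is not None else _VERSION_PRIORITY[self.version]

    def fixation_tolerance_for(self, eccentricity_deg: float) -> float:
        if self.fixation_tolerance_fn is not None:
            return float(self.fixation_tolerance_fn(eccentricity_deg))
        return self.fixation_tolerance_deg


@dataclass
class SessionResult:
    field: VisualField
    events: list
    complete: bool
    duration_s: float
    rng_seed: int
    test_version: str
    fp_rate: float | None = None
    incomplete_reason: str | None = None

    @property
    def n_presentations_total(self) -> int:
        return sum(1 for e in self.events if e["event"] == "presentation")


def seed_locations(pattern: TestPattern) -> tuple[FieldLocation, ...]:
    """The four growth-pattern seed points, one per quadrant (at +/-9, +/-9)."""
    out = []
    for x, y in SEED_COORDS:
        out.append(pattern.locations[pattern.index_of(x, y)])
    return tuple(out)


def _clamp_level(level: int) -> int:
    return int(min(max(level, DB_FLOOR), DB_CEILING))


def starting_level(
    neighbor_thresholds: Sequence[float],
    version: str,
    is_seed: bool = False,
    seed_start_db: int = 25,
) -> int:
    """Starting stimulus level for a location.

    Seeds use the fixed start; other locations start at the rounded mean
    (half away from zero) of their finished neighbours' thresholds.  v2
    additionally clamps starting levels to >= 18 dB.
    """
    if is_seed:
        level = int(seed_start_db)
    else:
        if len(neighbor_thresholds) == 0:
            raise SchedulingError("no finished neighbour to set a starting level")
        level = int(math.floor(float(np.mean(neighbor_thresholds)) + 0.5))
    level = _clamp_level(level)
    if version == "v2":
        level = max(level, 18)
    return level


def staircase_update(state: StaircaseState, response: str) -> StaircaseState:
    """Advance a 4-2 staircase by one response (mutates and returns state)."""
    if state.finished:
        raise StaircaseError("staircase already finished")
    if response not in ("seen", "unseen"):
        raise ValueError(f"response must be 'seen' or 'unseen', got {response!r}")

    level = state.current_level_db
    if state.last_response is not None and response != state.last_response:
        state.n_reversals += 1
    if response == "seen":
        state._last_seen_level = level
        state._ceiling_seen_streak = state._ceiling_seen_streak + 1 if level == DB_CEILING else 0
        state._floor_unseen_streak = 0
    else:
        state._floor_unseen_streak = state._floor_unseen_streak + 1 if level == DB_FLOOR else 0
        state._ceiling_seen_streak = 0
    state.last_response = response
    state.n_presentations += 1

    if state.n_reversals >= 2:
        state.finished = True
        state.threshold_db = float(state._last_seen_level)
        return state
    if state._floor_unseen_streak >= 2:
        state.finished = True
        state.threshold_db = float(DB_FLOOR)
        state.unmeasurable = True
        return state
    if state._ceiling_seen_streak >= 2:
        state.finished = True
        state.threshold_db = float(DB_CEILING)
        return state

    step = 4 if state.n_reversals == 0 else 2
    state.current_level_db = _clamp_level(level + step if response == "seen" else level - step)
    return state


def _finished_neighbor_thresholds(
    states: Sequence[StaircaseState],
    neighbor_map: dict[int, tuple[int, ...]],
    i: int,
    measurable_only: bool = False,
) -> list[float]:
    return [
        states[j].threshold_db
        for j in neighbor_map[i]
        if states[j].finished
        and states[j].threshold_db is not None
        and not (measurable_only and states[j].unmeasurable)
    ]


def _propagated_start_levels(
    states: Sequence[StaircaseState],
    neighbor_map: dict[int, tuple[int, ...]],
    st: StaircaseState,
) -> list[float]:
    """Thresholds the starting level is propagated from.

    Unmeasurable (floor-saturated) results carry no information about a
    neighbour's sensitivity, so they are skipped: first the measurable
    finished 4-neighbours, else the nearest finished measurable location,
    else nothing (the caller falls back to the seed start).
    """
    vals = _finished_neighbor_thresholds(states, neighbor_map, st.index, measurable_only=True)
    if vals:
        return vals
    done = [
        s for s in states
        if s.finished and s.threshold_db is not None and not s.unmeasurable
    ]
    if not done:
        return []
    x0, y0 = st.location.x_deg, st.location.y_deg
    nearest = min(done, key=lambda s: (s.location.x_deg - x0) ** 2 + (s.location.y_deg - y0) ** 2)
    return [nearest.threshold_db]


def _project_or_none(loc, fixation_xy, pose, screen, diameter_deg):
    try:
        xy = project_stimulus(loc.xy, pose, fixation_xy, screen=screen)
        radius = project_size(diameter_deg, pose, xy) / 2.0
        if not screen.contains(xy, margin_mm=radius):
            return None
        return xy
    except OffScreenError:
        return None


def eligible_locations(
    pending_states: Sequence[StaircaseState],
    fixation_screen_xy,
    eye_pose: EyePose,
    screen: ScreenModel,
    neighbor_map: dict[int, tuple[int, ...]] | None = None,
    all_states: Sequence[StaircaseState] | None = None,
    diameter_deg: float = 0.43,
) -> list[StaircaseState]:
    """Unfinished locations currently testable: the stimulus projects fully
    on-screen from the present fixation point and eye pose, and (for
    non-seeds) at least one 4-neighbour has a finished threshold."""
    all_states = all_states if all_states is not None else pending_states
    out = []
    for st in pending_states:
        if st.finished:
            continue
        if not st.is_seed and neighbor_map is not None:
            if not _finished_neighbor_thresholds(all_states, neighbor_map, st.index):
                continue
        if _project_or_none(st.location, fixation_screen_xy, eye_pose, screen, diameter_deg) is None:
            continue
        out.append(st)
    return out


def _recenter_fixation(
    pending, all_states, eye_pose, screen, neighbor_map, diameter_deg
) -> tuple[float, float]:
    """Fixation point maximising the number of eligible locations (coarse
    grid search; ties prefer the screen centre)."""
    xs = np.linspace(-screen.width_mm / 2 * 0.8, screen.width_mm / 2 * 0.8, 7)
    ys = np.linspace(-screen.height_mm / 2 * 0.8, screen.height_mm / 2 * 0.8, 7)
    best, best_n, best_d = (0.0, 0.0), -1, np.inf
    for x in xs:
        for y in ys:
            n = len(
                eligible_locations(
                    pending, (x, y), eye_pose, screen,
                    neighbor_map=neighbor_map, all_states=all_states,
                    diameter_deg=diameter_deg,
                )
            )
            d = math.hypot(x, y)
            if n > best_n or (n == best_n and d < best_d):
                best, best_n, best_d = (float(x), float(y)), n, d
    return best


def _build_states(pattern: TestPattern, seed_start_db: int) -> list[StaircaseState]:
    seed_xy = set(SEED_COORDS)
    return [
        StaircaseState(
            location=loc,
            index=i,
            is_seed=(loc.x_deg, loc.y_deg) in seed_xy,
            current_level_db=seed_start_db,
        )
        for i, loc in enumerate(pattern)
    ]


def _result_from_states(
    pattern, states, config_version, events, clock_ms, complete, rng_seed,
    fp_rate=None, reason=None,
) -> SessionResult:
    thresholds = np.array(
        [s.threshold_db if s.threshold_db is not None else np.nan for s in states]
    )
    n_pres = np.array([s.n_presentations for s in states])
    vf = VisualField(
        pattern=pattern,
        thresholds_db=thresholds,
        test_version=config_version,
        n_presentations=n_pres,
        duration_s=clock_ms / 1000.0,
    )
    return SessionResult(
        field=vf,
        events=events,
        complete=complete and vf.complete,
        duration_s=clock_ms / 1000.0,
        rng_seed=rng_seed,
        test_version=config_version,
        fp_rate=fp_rate,
        incomplete_reason=reason,
    )


def _choose(rng, elig, wait_counts, weight):
    if weight <= 0 or len(elig) == 1:
        return elig[int(rng.integers(len(elig)))]
    w = np.array([1.0 + weight * wait_counts.get(st.index, 0) for st in elig])
    return elig[int(rng.choice(len(elig), p=w / w.sum()))]


def run_session(config: SessionConfig, observer: ObserverModel) -> SessionResult:
    """Run a full gaze-driven threshold test against a synthetic observer.

    The loop: pick an eligible location, verify fixation on the current
    fixation target, project and present the stimulus, classify the gaze
    response, update that location's staircase.  A seen stimulus becomes
    the next fixation target.  Persistent tracking failure beyond the
    retry budget yields an incomplete (never an exception) result.
    """
    pattern = observer.pattern
    if pattern.pattern_name != config.pattern_name or pattern.eye != config.eye:
        raise ValueError("observer pattern does not match session config")
    diameter_deg = config.stimulus.diameter_deg
    neighbor_map = {i: pattern.neighbor_indices(i) for i in range(len(pattern))}
    states = _build_states(pattern, config.seed_start_db)

    sched_rng = np.random.default_rng([config.rng_seed, 0])
    obs_rng = np.random.default_rng([observer.rng_seed, config.rng_seed, 1])

    events: list[dict] = []
    clock_ms = 0.0
    fixation = (0.0, 0.0)
    pose = EyePose()
    failures = 0
    recenter_streak = 0
    wait_counts: dict[int, int] = {}
    max_presentations = 40 * len(pattern)
    n_pres_total = 0

    def unfinished():
        return [s for s in states if not s.finished]

    while unfinished():
        if n_pres_total >= max_presentations:
            return _result_from_states(
                pattern, states, config.version, events, clock_ms, False,
                config.rng_seed, reason="presentation budget exhausted",
            )
        pending = [s for s in states if not s.finished]
        if any(s.is_seed for s in pending):
            pending = [s for s in pending if s.is_seed]
        elig = eligible_locations(
            pending, fixation, pose, config.screen,
            neighbor_map=neighbor_map, all_states=states, diameter_deg=diameter_deg,
        )
        if not elig:
            recenter_streak += 1
            if recenter_streak > 2:
                return _result_from_states(
                    pattern, states, config.version, events, clock_ms, False,
                    config.rng_seed, reason="no eligible locations",
                )
            fixation = _recenter_fixation(
                pending, states, pose, config.screen, neighbor_map, diameter_deg
            )
            events.append({"event": "recenter", "t_ms": clock_ms,
                           "fixation_xy_mm": fixation})
            clock_ms += 500.0
            continue
        recenter_streak = 0
        st = _choose(sched_rng, elig, wait_counts, config.scheduling_priority_weight)
        for other in elig:
            if other is not st:
                wait_counts[other.index] = wait_counts.get(other.index, 0) + 1
        wait_counts[st.index] = 0

        # fixation gate
        tol = config.fixation_tolerance_for(st.location.eccentricity_deg)
        fix_stream = synthesize_fixation(
            observer, fixation, config.dwell_ms, pose, rng=obs_rng, t0_ms=clock_ms
        )
        try:
            fixating = verify_fixation(
                fix_stream, fixation, tolerance_deg=tol, dwell_ms=config.dwell_ms
            )
        except TrackingLossError:
            fixating = False
        clock_ms = float(fix_stream.t_ms[-1])
        pose = fix_stream.final_pose
        events.append({"event": "fixation_check", "t_ms": clock_ms, "passed": fixating,
                       "fixation_xy_mm": tuple(map(float, fixation))})
        if not fixating:
            failures += 1
            if failures > config.retry_budget:
                return _result_from_states(
                    pattern, states, config.version, events, clock_ms, False,
                    config.rng_seed, reason="tracking loss beyond retry budget",
                )
            continue

        if not st.started:
            levels = [] if st.is_seed else _propagated_start_levels(states, neighbor_map, st)
            st.current_level_db = starting_level(
                levels,
                config.version,
                is_seed=st.is_seed or not levels,
                seed_start_db=config.seed_start_db,
            )
            st.started = True

        screen_xy = _project_or_none(
            st.location, fixation, pose, config.screen, diameter_deg
        )
        if screen_xy is None:  # pose drifted since the eligibility check
            continue
        luminance = db_to_increment(st.current_level_db) + config.stimulus.background_cdm2

        intent = respond(observer, st.index, st.current_level_db, rng=obs_rng)
        stream = synthesize_gaze(
            observer, intent, fixation, screen_xy,
            window_ms=config.unseen_window_ms, eye_pose=pose, rng=obs_rng,
            t0_ms=clock_ms,
        )
        decision = classify_response(
            stream, fixation, screen_xy, onset_ms=clock_ms,
            window_ms=config.unseen_window_ms,
            direction_tol_deg=config.direction_tol_deg,
            amplitude_tol_frac=config.amplitude_tol_frac,
            fixation_tol_deg=tol,
        )
        n_pres_total += 1
        events.append({
            "event": "presentation", "t_ms": clock_ms, "index": st.index,
            "x_deg": st.location.x_deg, "y_deg": st.location.y_deg,
            "level_db": st.current_level_db, "luminance_cdm2": luminance,
            "screen_xy_mm": tuple(map(float, screen_xy)),
            "fixation_xy_mm": tuple(map(float, fixation)),
            "eye_pose_mm": tuple(pose.as_array()),
            "outcome": decision.outcome,
            "latency_ms": decision.saccade_latency_ms,
        })
        pose = stream.final_pose
        if decision.outcome == "invalid":
            st.n_presentations += 1
            clock_ms += config.stimulus.duration_ms + config.unseen_window_ms
            failures += 1
            if failures > config.retry_budget:
                return _result_from_states(
                    pattern, states, config.version, events, clock_ms, False,
                    config.rng_seed, reason="tracking loss beyond retry budget",
                )
            continue
        failures = 0
        staircase_update(st, decision.outcome)
        if decision.outcome == "seen":
            clock_ms += config.stimulus.duration_ms + (decision.saccade_latency_ms or 0.0) + 300.0
            fixation = (float(screen_xy[0]), float(screen_xy[1]))
        else:
            clock_ms += config.stimulus.duration_ms + config.unseen_window_ms

    return _result_from_states(
        pattern, states, config.version, events, clock_ms, True, config.rng_seed
    )


def run_sap_like_session(config: SessionConfig, observer: ObserverModel) -> SessionResult:
    """Button-response comparator: the same 4-2 engine and growth pattern
    with no gaze layer.  The observer's false-positive rate is carried on
    the result for the analysis module's exclusion rule."""
    pattern = observer.pattern
    if pattern.pattern_name != config.pattern_name or pattern.eye != config.eye:
        raise ValueError("observer pattern does not match session config")
    neighbor_map = {i: pattern.neighbor_indices(i) for i in range(len(pattern))}
    states = _build_states(pattern, config.seed_start_db)
    sched_rng = np.random.default_rng([config.rng_seed, 2])
    obs_rng = np.random.default_rng([observer.rng_seed, config.rng_seed, 3])
    events: list[dict] = []
    clock_ms = 0.0

    while True:
        pending = [s for s in states if not s.finished]
        if not pending:
            break
        if any(s.is_seed for s in pending):
            elig = [s for s in pending if s.is_seed]
        else:
            elig = [
                s for s in pending
                if _finished_neighbor_thresholds(states, neighbor_map, s.index)
            ]
        st = elig[int(sched_rng.integers(len(elig)))]
        if not st.started:
            levels = [] if st.is_seed else _propagated_start_levels(states, neighbor_map, st)
            st.current_level_db = starting_level(
                levels,
                config.version,
                is_seed=st.is_seed or not levels,
                seed_start_db=config.seed_start_db,
            )
            st.started = True
        outcome = respond(observer, st.index, st.current_level_db, rng=obs_rng)
        events.append({
            "event": "presentation", "t_ms": clock_ms, "index": st.index,
            "x_deg": st.location.x_deg, "y_deg": st.location.y_deg,
            "level_db": st.current_level_db, "outcome": outcome,
        })
        staircase_update(st, outcome)
        clock_ms += config.stimulus.duration_ms + 1300.0

    result = _result_from_states(
        pattern, states, "sap_sim", events, clock_ms, True, config.rng_seed,
        fp_rate=observer.fp_rate,
    )
    return result
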