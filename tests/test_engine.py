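import dataclasses
import itertools

import numpy as np
import pytest

from conftest import replay_4_2, run_staircase_against_step_observer
from svopsim.engine import (
    SchedulingError,
    SessionConfig,
    StaircaseError,
    StaircaseState,
    eligible_locations,
    run_sap_like_session,
    run_session,
    seed_locations,
    staircase_update,
    starting_level,
)
from svopsim.field import StimulusSpec, generate_pattern
from svopsim.observer import ObserverModel, make_normal_field
from svopsim.projection import EyePose, ScreenModel, angular_offset


def make_state(start=25, pattern=None):
    pattern = pattern or generate_pattern("24-2", "right")
    return StaircaseState(
        location=pattern.locations[0], index=0, current_level_db=start, started=True
    )


def flat_observer(pattern, level=25.0, seed=1, noiseless=True):
    tf = np.full(54, float(level))
    tf[list(pattern.blind_spot_indices)] = 0.0
    obs = ObserverModel(pattern=pattern, true_field=tf, rng_seed=seed)
    return obs.noiseless() if noiseless else obs


class TestSeedLocations:
    def test_one_per_quadrant(self, pattern_right):
        seeds = seed_locations(pattern_right)
        assert len(seeds) == 4
        signs = {(np.sign(s.x_deg), np.sign(s.y_deg)) for s in seeds}
        assert signs == {(1, 1), (1, -1), (-1, 1), (-1, -1)}

    def test_no_blind_spot_seed(self, pattern_right):
        assert all(not s.is_blind_spot for s in seed_locations(pattern_right))


class TestStartingLevel:
    def test_rounded_mean(self):
        assert starting_level([30, 28], "v2") == 29

    def test_v2_floor_clamp(self):
        assert starting_level([14, 15], "v2") == 18

    def test_v1_unclamped_half_up_rounding(self):
        assert starting_level([14, 15], "v1") == 15

    def test_seed_uses_fixed_start(self):
        assert starting_level([], "v1", is_seed=True) == 25
        assert starting_level([], "v2", is_seed=True, seed_start_db=20) == 20

    def test_empty_neighbors_error(self):
        with pytest.raises(SchedulingError):
            starting_level([], "v1")


class TestStaircaseOracle:
    def test_worked_example(self):
        st = make_state(25)
        for r in ("seen", "seen", "unseen", "seen"):
            staircase_update(st, r)
        assert st.finished and st.threshold_db == 31.0

    def test_all_unseen_saturates_at_floor(self):
        st = make_state(25)
        while not st.finished:
            staircase_update(st, "unseen")
        assert st.threshold_db == 14.0 and st.unmeasurable

    def test_all_seen_saturates_at_ceiling(self):
        st = make_state(25)
        while not st.finished:
            staircase_update(st, "seen")
        assert st.threshold_db == 40.0 and not st.unmeasurable

    def test_update_after_finished_raises(self):
        st = make_state(25)
        while not st.finished:
            staircase_update(st, "unseen")
        with pytest.raises(StaircaseError):
            staircase_update(st, "seen")

    def test_bad_response_rejected(self):
        with pytest.raises(ValueError):
            staircase_update(make_state(), "perhaps")

    @pytest.mark.parametrize("start", [14, 18, 25, 33, 40])
    def test_exhaustive_equivalence_with_replay(self, start):
        """Engine agrees with the independent transcript replay on every
        response sequence to depth 12, including level trajectories."""
        for depth in range(1, 13):
            for seq in itertools.product(("seen", "unseen"), repeat=depth):
                status, thr, n_used, levels = replay_4_2(start, seq)
                st = make_state(start)
                engine_levels = []
                for i, r in enumerate(seq):
                    if st.finished:
                        break
                    engine_levels.append(st.current_level_db)
                    staircase_update(st, r)
                assert engine_levels == levels[: len(engine_levels)]
                if status == "running":
                    assert not st.finished
                else:
                    assert st.finished
                    assert st.threshold_db == thr
                    assert st.n_presentations == n_used
                    assert st.unmeasurable == (status == "floor")

    def test_deterministic_step_observer_recovery(self):
        """Step observer (seen iff level <= t): estimate within 2 dB of t
        for every integer truth 15..39 and every start 18..30."""
        for t in range(15, 40):
            for start in range(18, 31):
                est = run_staircase_against_step_observer(start, t)
                assert abs(est - t) <= 2, (t, start, est)


class TestEligibility:
    def make_states(self, pattern):
        from svopsim.engine import _build_states

        return _build_states(pattern, 25)

    def test_central_points_eligible_from_center(self, pattern_right):
        states = self.make_states(pattern_right)
        nmap = {i: pattern_right.neighbor_indices(i) for i in range(54)}
        elig = eligible_locations(
            [s for s in states if s.is_seed], (0.0, 0.0), EyePose(), ScreenModel(),
            neighbor_map=nmap, all_states=states,
        )
        assert len(elig) == 4

    def test_superior_points_ineligible_from_top_edge(self, pattern_right):
        states = self.make_states(pattern_right)
        screen = ScreenModel()
        nmap = {i: pattern_right.neighbor_indices(i) for i in range(54)}
        for s in states:
            s.is_seed = True  # isolate the geometric criterion
        top = (0.0, screen.height_mm / 2 - 10.0)
        elig = eligible_locations(states, top, EyePose(), screen,
                                  neighbor_map=nmap, all_states=states)
        ys = [s.location.y_deg for s in elig]
        assert not any(y > 9 for y in ys)  # superior field needs room above fixation
        assert any(y < 0 for y in ys)

    def test_all_finished_empty(self, pattern_right):
        states = self.make_states(pattern_right)
        for s in states:
            s.finished = True
            s.threshold_db = 25.0
        assert (
            eligible_locations(states, (0.0, 0.0), EyePose(), ScreenModel()) == []
        )

    def test_non_seed_requires_finished_neighbor(self, pattern_right):
        states = self.make_states(pattern_right)
        nmap = {i: pattern_right.neighbor_indices(i) for i in range(54)}
        elig = eligible_locations(states, (0.0, 0.0), EyePose(), ScreenModel(),
                                  neighbor_map=nmap, all_states=states)
        assert all(s.is_seed for s in elig)


class TestRunSession:
    def test_ideal_observer_recovery_within_2db(self, pattern_right):
        tf = np.clip(
            np.round(make_normal_field(pattern_right, rng=np.random.default_rng(5))),
            15, 39,
        )
        tf[list(pattern_right.blind_spot_indices)] = 0.0
        obs = ObserverModel(pattern=pattern_right, true_field=tf, rng_seed=5).noiseless()
        res = run_session(SessionConfig(rng_seed=9), obs)
        assert res.complete
        nb = list(pattern_right.non_blind_spot_indices)
        assert np.nanmax(np.abs(res.field.thresholds_db[nb] - tf[nb])) <= 2.0

    def test_full_dropout_incomplete_without_exception(self, pattern_right):
        obs = dataclasses.replace(flat_observer(pattern_right, noiseless=False),
                                  dropout_prob=1.0)
        res = run_session(SessionConfig(rng_seed=1, retry_budget=5), obs)
        assert not res.complete
        assert np.all(np.isnan(res.field.thresholds_db))
        assert res.incomplete_reason is not None

    def test_v2_first_presentation_never_below_18(self, pattern_right):
        # an observer with a deep defect drives propagated starts downward
        tf = np.full(54, 16.0)
        tf[list(pattern_right.blind_spot_indices)] = 0.0
        obs = ObserverModel(pattern=pattern_right, true_field=tf, rng_seed=3).noiseless()
        res = run_session(SessionConfig(version="v2", rng_seed=3), obs)
        first = {}
        for e in res.events:
            if e["event"] == "presentation" and e["index"] not in first:
                first[e["index"]] = e["level_db"]
        assert min(first.values()) >= 18

    def test_v1_first_presentation_may_go_below_18(self, pattern_right):
        tf = np.full(54, 16.0)
        tf[list(pattern_right.blind_spot_indices)] = 0.0
        obs = ObserverModel(pattern=pattern_right, true_field=tf, rng_seed=3).noiseless()
        res = run_session(SessionConfig(version="v1", rng_seed=3), obs)
        first = {}
        for e in res.events:
            if e["event"] == "presentation" and e["index"] not in first:
                first[e["index"]] = e["level_db"]
        assert min(first.values()) < 18

    def test_fixation_gating_invariant(self, pattern_right):
        obs = flat_observer(pattern_right, noiseless=False, seed=8)
        res = run_session(SessionConfig(rng_seed=8), obs)
        prev = None
        for e in res.events:
            if e["event"] == "presentation":
                assert prev is not None
                assert prev["event"] == "fixation_check" and prev["passed"]
            prev = e

    def test_gaze_contingency_invariant(self, pattern_right):
        obs = flat_observer(pattern_right, noiseless=False, seed=8)
        res = run_session(SessionConfig(rng_seed=8), obs)
        checked = 0
        for e in res.events:
            if e["event"] != "presentation":
                continue
            pose = EyePose(*e["eye_pose_mm"])
            back = angular_offset(e["screen_xy_mm"], pose, e["fixation_xy_mm"])
            np.testing.assert_allclose(back, (e["x_deg"], e["y_deg"]), atol=1e-6)
            checked += 1
        assert checked > 50

    def test_seen_stimulus_becomes_next_fixation(self, pattern_right):
        obs = flat_observer(pattern_right)
        res = run_session(SessionConfig(rng_seed=2), obs)
        expected = None  # fixation holds between events unless recentred
        for e in res.events:
            if e["event"] == "recenter":
                expected = tuple(e["fixation_xy_mm"])
            elif e["event"] == "presentation":
                if expected is not None:
                    assert tuple(e["fixation_xy_mm"]) == expected
                if e["outcome"] == "seen":
                    expected = tuple(e["screen_xy_mm"])

    def test_presentation_counts_match_log(self, pattern_right):
        obs = flat_observer(pattern_right, noiseless=False, seed=6)
        res = run_session(SessionConfig(rng_seed=6), obs)
        from collections import Counter

        log_counts = Counter(
            e["index"] for e in res.events if e["event"] == "presentation"
        )
        for i in range(54):
            assert res.field.n_presentations[i] == log_counts.get(i, 0)

    def test_seeds_tested_first(self, pattern_right):
        obs = flat_observer(pattern_right)
        res = run_session(SessionConfig(rng_seed=4), obs)
        seed_xy = {s.xy for s in seed_locations(pattern_right)}
        pres = [e for e in res.events if e["event"] == "presentation"]
        seen_nonseed = False
        for e in pres:
            if (e["x_deg"], e["y_deg"]) in seed_xy:
                assert not seen_nonseed, "seed tested after non-seed started"
            else:
                seen_nonseed = True

    def test_determinism(self, pattern_right):
        obs = flat_observer(pattern_right, noiseless=False, seed=5)
        r1 = run_session(SessionConfig(rng_seed=13), obs)
        r2 = run_session(SessionConfig(rng_seed=13), obs)
        np.testing.assert_array_equal(r1.field.thresholds_db, r2.field.thresholds_db)
        assert r1.duration_s == r2.duration_s
        assert len(r1.events) == len(r2.events)


class TestSapLikeSession:
    def test_ideal_observer_recovery(self, pattern_right):
        tf = np.clip(
            np.round(make_normal_field(pattern_right, rng=np.random.default_rng(7))),
            15, 39,
        )
        tf[list(pattern_right.blind_spot_indices)] = 0.0
        obs = ObserverModel(pattern=pattern_right, true_field=tf, rng_seed=7).noiseless()
        res = run_sap_like_session(SessionConfig(rng_seed=7), obs)
        assert res.complete and res.test_version == "sap_sim"
        nb = list(pattern_right.non_blind_spot_indices)
        assert np.nanmax(np.abs(res.field.thresholds_db[nb] - tf[nb])) <= 2.0

    def test_false_positive_rate_recorded(self, pattern_right):
        obs = dataclasses.replace(flat_observer(pattern_right, noiseless=False),
                                  fp_rate=0.2)
        res = run_sap_like_session(SessionConfig(rng_seed=1), obs)
        assert res.fp_rate == pytest.approx(0.2)
        assert res.fp_rate > 0.15  # above the exclusion bound

    def test_determinism(self, pattern_right):
        obs = flat_observer(pattern_right, noiseless=False, seed=2)
        r1 = run_sap_like_session(SessionConfig(rng_seed=21), obs)
        r2 = run_sap_like_session(SessionConfig(rng_seed=21), obs)
        np.testing.assert_array_equal(r1.field.thresholds_db, r2.field.thresholds_db)
        assert [e["level_db"] for e in r1.events] == [e["level_db"] for e in r2.events]


class TestSessionConfig:
    def test_version_defaults(self):
        assert SessionConfig(version="v1").dwell_ms == 200.0
        assert SessionConfig(version="v2").dwell_ms == 500.0
        assert SessionConfig(version="v1").scheduling_priority_weight == 0.0
        assert SessionConfig(version="v2").scheduling_priority_weight > 0.0

    def test_bad_version_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(version="v3")

    def test_eccentricity_dependent_tolerance_hook(self):
        cfg = SessionConfig(fixation_tolerance_fn=lambda ecc: 1.0 + ecc / 10.0)
        assert cfg.fixation_tolerance_for(10.0) == pytest.approx(2.0)
        assert SessionConfig().fixation_tolerance_for(10.0) == 2.0
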