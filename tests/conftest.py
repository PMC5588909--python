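import numpy as np
import pytest

from svopsim.field import generate_pattern


@pytest.fixture(scope="session")
def pattern_right():
    return generate_pattern("24-2", "right")


@pytest.fixture(scope="session")
def pattern_left():
    return generate_pattern("24-2", "left")


def replay_4_2(start, responses, floor=14, ceiling=40):
    """Independent transcript-style replay of the 4-2 bracketing rules.

    Steps 4 dB until the first reversal then 2 dB; terminates at the second
    reversal with threshold = last seen level, or after two consecutive
    unseen at the floor (floor, unmeasurable) / seen at the ceiling.
    Returns (status, threshold, n_used, levels) where levels[i] is the
    level presented for responses[i].
    """
    level = start
    levels = [start]
    resps = []
    seen_levels = []
    reversals = 0
    for r in responses:
        resps.append(r)
        if len(resps) >= 2 and resps[-1] != resps[-2]:
            reversals += 1
        if r == "seen":
            seen_levels.append(level)
        if reversals >= 2:
            return ("threshold", float(seen_levels[-1]), len(resps), levels)
        if (
            len(resps) >= 2
            and resps[-1] == resps[-2] == "unseen"
            and levels[-1] == levels[-2] == floor
        ):
            return ("floor", float(floor), len(resps), levels)
        if (
            len(resps) >= 2
            and resps[-1] == resps[-2] == "seen"
            and levels[-1] == levels[-2] == ceiling
        ):
            return ("ceiling", float(ceiling), len(resps), levels)
        step = 4 if reversals == 0 else 2
        level = level + step if r == "seen" else level - step
        level = max(floor, min(ceiling, level))
        levels.append(level)
    return ("running", None, len(resps), levels)


def run_staircase_against_step_observer(start, true_db):
    """Drive the engine's staircase with a deterministic seen-iff-level<=t
    observer until it finishes; returns the threshold estimate."""
    from svopsim.engine import StaircaseState, staircase_update
    from svopsim.field import generate_pattern

    loc = generate_pattern("24-2", "right").locations[0]
    st = StaircaseState(location=loc, index=0, current_level_db=start, started=True)
    while not st.finished:
        staircase_update(st, "seen" if st.current_level_db <= true_db else "unseen")
    return st.threshold_db
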