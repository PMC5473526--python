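import numpy as np
import pytest

from autoprt.subject_sim import CohortSpec, simulate_cohort
from autoprt.task_engine import PressAttempt, TaskConfig, TaskVariant


@pytest.fixture(scope="session")
def default_cohort():
    """The default 16-subject cohort at the default master seed (shared)."""
    return simulate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 6-subject cohort with a short itinerary, for fast structural tests."""
    spec = CohortSpec(
        n_users=2, n_non_users=2, n_unexposed=2,
        bf_sessions=4, rf_sessions=6, lab_sessions=8,
        bf_session_min=20, rf_session_min=20,
        master_seed=7,
    )
    return simulate_cohort(spec)


def make_success_log(k, *, facility="BF", subject_id="S00", session_index=1,
                     variant=TaskVariant.ONE_BUTTON, gap_ms=4000, hold_ms=200,
                     session_cap_ms=30 * 60_000, rng_seed=0):
    """A session log with exactly k successful presses and nothing else.

    The scripted subject always presses the currently cued button (button 1
    on the any-button task) and holds long enough.
    """
    from autoprt.task_engine import SessionLog, init_session, score_press

    cfg = TaskConfig(
        task_variant=variant, n_buttons=4, session_cap_ms=session_cap_ms,
        rng_seed=rng_seed,
    )
    state = init_session(cfg)
    for i in range(k):
        button = state.cue if isinstance(state.cue, int) else 1
        score_press(state, PressAttempt(button, 1000 + i * gap_ms, hold_ms), cfg)
    log = SessionLog(
        subject_id=subject_id, facility=facility, session_index=session_index,
        start=state.start, config=cfg, actual_duration_ms=session_cap_ms,
        trials=state.trial_history,
    )
    assert log.successes == k
    return log


def random_press_script(rng: np.random.Generator, config: TaskConfig, n: int):
    """A random valid (ordered, non-overlapping) press script."""
    presses = []
    t = 0
    for _ in range(n):
        t += int(rng.integers(1, 6000))
        duration = int(rng.integers(1, 400))
        button = int(rng.integers(1, config.n_buttons + 1))
        presses.append(PressAttempt(button, t, duration))
        t += duration
    return presses
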