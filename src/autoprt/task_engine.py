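"""Deterministic discrete-event engine for the cued button-press task.

A session presents one illuminated LED cue at a time. A press of the cued
button held continuously for at least ``hold_time_ms`` is a SUCCESS and earns
a reward; pressing another button (WRONG_BUTTON) or releasing the cued button
too soon (EARLY_RELEASE) triggers a time-out during which all cues are dark
and any press is scored TIMEOUT_PRESS and prolongs the time-out. After an
error the *same* cue re-illuminates and persists until correctly pressed,
which discourages stereotyped pressing of a single favourite button. After a
SUCCESS a fresh cue is drawn.

All times are integer milliseconds from session start; button ids are
1-based. The engine is fully deterministic given ``TaskConfig.rng_seed``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "ANY",
    "ConfigError",
    "EngineState",
    "InputError",
    "Outcome",
    "PressAttempt",
    "SessionLog",
    "SessionOver",
    "TaskConfig",
    "TaskVariant",
    "TimeoutPolicy",
    "init_session",
    "run_session",
    "score_press",
    "select_next_cue",
]

#: Cue sentinel for the 1-button task: any button press is rewardable.
ANY = "ANY"

#: Default session start used when no wall-clock schedule is supplied.
DEFAULT_SESSION_START = datetime(2021, 1, 4, 9, 0, 0)

Cue = Union[int, str]


class ConfigError(ValueError):
    """Raised for an invalid TaskConfig."""


class InputError(ValueError):
    """Raised for malformed press input (out of order, overlapping, ...)."""


class SessionOver(Exception):
    """Signals a press attempted at or beyond the session cap."""


class TaskVariant(enum.Enum):
    """Task difficulty level; the value is the number of active buttons."""

    ONE_BUTTON = 1
    TWO_BUTTON = 2
    FOUR_BUTTON = 4

    @property
    def active_buttons(self) -> int:
        return self.value


class TimeoutPolicy(enum.Enum):
    """How a press during an active time-out prolongs it.

    RESTART: the full time-out period restarts at the offending press.
    EXTEND: one extra time-out period is appended to the current deadline.
    """

    RESTART = "RESTART"
    EXTEND = "EXTEND"


class Outcome(enum.Enum):
    SUCCESS = "SUCCESS"
    WRONG_BUTTON = "WRONG_BUTTON"
    EARLY_RELEASE = "EARLY_RELEASE"
    TIMEOUT_PRESS = "TIMEOUT_PRESS"


@dataclass(frozen=True)
class TaskConfig:
    """All engine parameters for one session.

    ``hold_time_ms`` is the minimum continuous press duration that counts as
    successful (50 ms by default). ``timeout_ms`` is the post-error period
    with cues dark. ``refractory_ms`` optionally delays cue re-illumination
    after a reward (display-only; scoring is unaffected).
    """

    task_variant: TaskVariant = TaskVariant.FOUR_BUTTON
    n_buttons: int = 4
    hold_time_ms: int = 50
    timeout_ms: int = 3000
    timeout_prolong: TimeoutPolicy = TimeoutPolicy.RESTART
    session_cap_ms: int = 30 * 60_000
    reward_units_per_success: float = 0.5
    refractory_ms: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.hold_time_ms <= 0:
            raise ConfigError("hold_time_ms must be > 0")
        if self.timeout_ms < 0:
            raise ConfigError("timeout_ms must be >= 0")
        if self.session_cap_ms <= 0:
            raise ConfigError("session_cap_ms must be > 0")
        if self.refractory_ms < 0:
            raise ConfigError("refractory_ms must be >= 0")
        if self.task_variant.active_buttons > self.n_buttons:
            raise ConfigError(
                f"{self.task_variant.name} needs "
                f"{self.task_variant.active_buttons} buttons, device has "
                f"{self.n_buttons}"
            )


@dataclass(frozen=True)
class PressAttempt:
    """A raw button press: which button, when it went down, how long held."""

    button: int
    t_down_ms: int
    duration_ms: int

    def validate(self, n_buttons: int) -> None:
        if self.t_down_ms < 0:
            raise InputError("t_down_ms must be >= 0")
        if self.duration_ms <= 0:
            raise InputError("duration_ms must be > 0")
        if not 1 <= self.button <= n_buttons:
            raise InputError(
                f"button {self.button} outside [1, {n_buttons}]"
            )

    @property
    def t_up_ms(self) -> int:
        return self.t_down_ms + self.duration_ms


@dataclass(frozen=True)
class TrialRecord:
    """One scored press attempt, as logged by the device."""

    press: PressAttempt
    cued_button: Cue  # the (pending) cue at press time; ANY on 1-button task
    outcome: Outcome
    reward: bool
    timestamp: datetime

    def __post_init__(self) -> None:
        if self.reward != (self.outcome is Outcome.SUCCESS):
            raise InputError("reward must be true iff outcome is SUCCESS")


@dataclass
class EngineState:
    """Evolving session state: clock, lit cue, active time-out, history."""

    clock_ms: int
    cue: Cue
    timeout_until_ms: Optional[int]
    trial_history: List[TrialRecord]
    rng: np.random.Generator
    start: datetime = DEFAULT_SESSION_START

    @property
    def cue_visible(self) -> Union[Cue, None]:
        """The cue as the subject sees it: None (all dark) during a time-out."""
        if self.timeout_until_ms is not None and self.clock_ms < self.timeout_until_ms:
            return None
        return self.cue


def select_next_cue(state: EngineState, config: TaskConfig) -> Cue:
    """Draw the cue for the next trial.

    1-button task: ANY (every button is rewardable). Otherwise a uniform
    draw over the active buttons from the engine rng; immediate repeats are
    allowed.
    """
    if config.task_variant is TaskVariant.ONE_BUTTON:
        return ANY
    return int(state.rng.integers(1, config.task_variant.active_buttons + 1))


def init_session(config: TaskConfig, start: datetime = DEFAULT_SESSION_START) -> EngineState:
    """Start a session: clock at 0, rng seeded from config, a cue lit."""
    config.validate()
    state = EngineState(
        clock_ms=0,
        cue=ANY,
        timeout_until_ms=None,
        trial_history=[],
        rng=np.random.default_rng(config.rng_seed),
        start=start,
    )
    state.cue = select_next_cue(state, config)
    return state


def score_press(
    state: EngineState, press: PressAttempt, config: TaskConfig
) -> tuple[EngineState, TrialRecord]:
    """Score one press against the current engine state (mutates ``state``).

    Outcomes:
      * time-out active at press onset -> TIMEOUT_PRESS, time-out prolonged
        per ``timeout_prolong`` (RESTART: full period restarts at the press;
        EXTEND: one period appended to the current deadline);
      * cued button (or any button on the 1-button task) held for at least
        ``hold_time_ms`` -> SUCCESS at hold completion, reward, new cue;
      * wrong button -> WRONG_BUTTON, time-out starts at press onset and the
        same cue will re-illuminate afterwards;
      * cued button released early -> EARLY_RELEASE, time-out starts at
        release, same cue re-illuminates.
    """
    press.validate(config.n_buttons)
    if press.t_down_ms < state.clock_ms:
        raise InputError(
            f"press at {press.t_down_ms} ms precedes engine clock "
            f"{state.clock_ms} ms"
        )
    if press.t_down_ms >= config.session_cap_ms:
        raise SessionOver(
            f"press at {press.t_down_ms} ms is beyond the session cap "
            f"{config.session_cap_ms} ms"
        )

    timeout_active = (
        state.timeout_until_ms is not None
        and press.t_down_ms < state.timeout_until_ms
    )
    reward = False
    if timeout_active:
        outcome = Outcome.TIMEOUT_PRESS
        if config.timeout_prolong is TimeoutPolicy.RESTART:
            state.timeout_until_ms = press.t_down_ms + config.timeout_ms
        else:
            state.timeout_until_ms += config.timeout_ms  # type: ignore[operator]
    else:
        state.timeout_until_ms = None
        hit = state.cue == ANY or press.button == state.cue
        if hit and press.duration_ms >= config.hold_time_ms:
            outcome = Outcome.SUCCESS
            reward = True
        elif not hit:
            outcome = Outcome.WRONG_BUTTON
            state.timeout_until_ms = press.t_down_ms + config.timeout_ms
        else:
            outcome = Outcome.EARLY_RELEASE
            state.timeout_until_ms = press.t_up_ms + config.timeout_ms

    record = TrialRecord(
        press=press,
        cued_button=state.cue,
        outcome=outcome,
        reward=reward,
        timestamp=state.start + timedelta(milliseconds=press.t_down_ms),
    )
    state.trial_history.append(record)
    if outcome is Outcome.SUCCESS:
        state.cue = select_next_cue(state, config)
    state.clock_ms = press.t_up_ms
    return state, record


@dataclass
class SessionLog:
    """The complete record of one session: header metadata plus trials."""

    subject_id: str
    facility: str  # BF | RF | LAB
    session_index: int  # 1-based within facility
    start: datetime
    config: TaskConfig
    actual_duration_ms: int
    trials: List[TrialRecord] = field(default_factory=list)
    annotation: str = ""

    @property
    def attempts(self) -> int:
        return len(self.trials)

    @property
    def successes(self) -> int:
        return sum(1 for t in self.trials if t.outcome is Outcome.SUCCESS)

    def outcome_counts(self) -> dict:
        counts = {o: 0 for o in Outcome}
        for t in self.trials:
            counts[t.outcome] += 1
        return counts


def _check_script(presses: Sequence[PressAttempt], config: TaskConfig) -> None:
    prev_up = 0
    for i, p in enumerate(presses):
        p.validate(config.n_buttons)
        if p.t_down_ms < prev_up:
            raise InputError(
                f"press {i} at {p.t_down_ms} ms overlaps or precedes the "
                f"previous press (ended {prev_up} ms)"
            )
        prev_up = p.t_up_ms


def run_session(
    config: TaskConfig,
    presses: Sequence[PressAttempt],
    *,
    subject_id: str = "S00",
    facility: str = "RF",
    session_index: int = 1,
    start: datetime = DEFAULT_SESSION_START,
    actual_duration_ms: Optional[int] = None,
    annotation: str = "",
) -> SessionLog:
    """Replay a time-ordered, non-overlapping press script through the engine.

    Presses at or beyond the session cap are dropped (session over). Returns
    the full SessionLog; every replayed press yields exactly one TrialRecord.
    """
    config.validate()
    _check_script(presses, config)
    state = init_session(config, start)
    for press in presses:
        try:
            score_press(state, press, config)
        except SessionOver:
            break
    return SessionLog(
        subject_id=subject_id,
        facility=facility,
        session_index=session_index,
        start=start,
        config=config,
        actual_duration_ms=(
            config.session_cap_ms if actual_duration_ms is None else actual_duration_ms
        ),
        trials=state.trial_history,
        annotation=annotation,
    )
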