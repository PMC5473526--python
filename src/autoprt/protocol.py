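"""Training-progression rules across the three facilities.

Breeding facility (BF): 1-button task only (group exposure, then individual
sessions). Research facility (RF): subjects start on the task settings they
last used at the BF and progress from the 1-button to the 4-button task once
they meet the performance criterion (default: >= 100 successful presses in a
single session). Laboratory (LAB): session duration ramps linearly from 10 to
36 minutes over the first 8 sessions, and subjects progress from the 1-button
to the 2-button task under the same criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .task_engine import InputError, SessionLog, TaskVariant

__all__ = [
    "DEFAULT_STAGE_ORDER",
    "ProgressionBasis",
    "ProtocolConfig",
    "lab_session_cap",
    "next_task_stage",
    "should_progress",
]


class ProgressionBasis(Enum):
    PER_SESSION = "PER_SESSION"  # successes in a single session
    PER_HOUR = "PER_HOUR"  # successes per actual hour of a session


DEFAULT_STAGE_ORDER: dict[str, tuple[TaskVariant, ...]] = {
    "BF": (TaskVariant.ONE_BUTTON,),
    "RF": (TaskVariant.ONE_BUTTON, TaskVariant.FOUR_BUTTON),
    "LAB": (TaskVariant.ONE_BUTTON, TaskVariant.TWO_BUTTON),
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Progression thresholds, BF phase lengths and the lab duration ramp.

    Durations are working days (5 per week); lab ramp endpoints in minutes.
    """

    progression_threshold: int = 100
    progression_basis: ProgressionBasis = ProgressionBasis.PER_SESSION
    bf_group_phase_min_days: int = 5
    bf_individual_phase_min_days: int = 10
    lab_ramp_start_min: int = 10
    lab_ramp_end_min: int = 36
    lab_ramp_sessions: int = 8
    stage_order: Mapping[str, tuple[TaskVariant, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_ORDER)
    )

    def validate(self) -> None:
        if self.progression_threshold <= 0:
            raise InputError("progression_threshold must be > 0")
        if self.lab_ramp_end_min < self.lab_ramp_start_min:
            raise InputError("lab ramp must not decrease")
        if self.lab_ramp_sessions < 2:
            raise InputError("lab_ramp_sessions must be >= 2")


def should_progress(
    session_logs: Sequence[SessionLog], cfg: Optional[ProtocolConfig] = None
) -> bool:
    """True iff any session in the current stage meets the criterion.

    PER_SESSION basis: successes in the session >= threshold.
    PER_HOUR basis: successes / actual session hours >= threshold.
    An empty history never progresses.
    """
    cfg = cfg or ProtocolConfig()
    cfg.validate()
    for log in session_logs:
        if cfg.progression_basis is ProgressionBasis.PER_SESSION:
            value = log.successes
        else:
            hours = log.actual_duration_ms / 3_600_000
            if hours <= 0:
                continue
            value = log.successes / hours
        if value >= cfg.progression_threshold:
            return True
    return False


def lab_session_cap(k: int, cfg: Optional[ProtocolConfig] = None) -> int:
    """Scheduled duration (minutes) of the k-th lab session, 1-based.

    Linear interpolation between the ramp endpoints, rounded half-up to the
    nearest minute; constant at the maximum beyond the ramp.
    """
    cfg = cfg or ProtocolConfig()
    cfg.validate()
    if k < 1:
        raise InputError("session index k must be >= 1")
    if k >= cfg.lab_ramp_sessions:
        return cfg.lab_ramp_end_min
    span = cfg.lab_ramp_end_min - cfg.lab_ramp_start_min
    x = cfg.lab_ramp_start_min + span * (k - 1) / (cfg.lab_ramp_sessions - 1)
    return int(math.floor(x + 0.5))


def next_task_stage(
    history: Mapping[TaskVariant, Sequence[SessionLog]],
    facility: str,
    cfg: Optional[ProtocolConfig] = None,
    *,
    incoming_stage: Optional[TaskVariant] = None,
) -> TaskVariant:
    """The task variant the subject should run next at ``facility``.

    ``history`` maps each task variant already trained at this facility to
    its session logs. With no history yet, a subject arriving from another
    facility continues on ``incoming_stage`` (the settings it last used);
    otherwise the facility's first stage. The stage advances one step in the
    facility's stage order when the current stage's history satisfies
    :func:`should_progress`; stages are never skipped.
    """
    cfg = cfg or ProtocolConfig()
    cfg.validate()
    try:
        order = cfg.stage_order[facility]
    except KeyError:
        raise InputError(f"unknown facility {facility!r}") from None

    trained = [v for v in order if history.get(v)]
    if not trained:
        if incoming_stage is not None:
            if incoming_stage not in order:
                # arriving stage not part of this facility's ladder: start over
                return order[0]
            return incoming_stage
        return order[0]
    current = trained[-1]
    idx = order.index(current)
    if idx + 1 < len(order) and should_progress(history[current], cfg):
        return order[idx + 1]
    return current
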