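"""Seeded generative model of subjects pressing buttons against the engine.

Each simulated subject is an operant-learning agent with an archetype
(USER / NON_USER / UNEXPOSED). Within a session the agent, if engaged,
emits presses at exponential inter-press intervals; it presses the cued
button with probability ``p_correct`` (uniform among the other active buttons
otherwise) and holds for a truncated-normal duration. Cue-following improves
with reward following an exponential learning curve in cumulative rewards:

    p_correct(r) = p_inf - (p_inf - p0) * exp(-r / tau)

Learning state persists across sessions and facilities. A full cohort is
simulated subject by subject through the breeding-facility, research-facility
and laboratory itineraries, with stage progression applied per subject by the
protocol rules. Everything is reproducible from one master seed.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import calibration
from .protocol import ProtocolConfig, lab_session_cap, next_task_stage
from .task_engine import (
    InputError,
    Outcome,
    PressAttempt,
    SessionLog,
    TaskConfig,
    TaskVariant,
    TrialRecord,
    init_session,
    score_press,
)

__all__ = [
    "AgentParams",
    "AgentState",
    "Archetype",
    "CohortDataset",
    "CohortSpec",
    "agent_act",
    "make_agent",
    "run_agent_session",
    "simulate_cohort",
    "update_agent",
]


class Archetype(enum.Enum):
    USER = "USER"
    NON_USER = "NON_USER"
    UNEXPOSED = "UNEXPOSED"


@dataclass(frozen=True)
class AgentParams:
    """A simulated subject's fixed behavioural parameters."""

    archetype: Archetype
    engage_rate_per_min: float  # presses attempted per engaged minute
    engage_prob: float  # per-session probability of interacting at all
    p0_correct: float  # initial cue-following probability
    p_inf_correct: float  # asymptotic cue-following probability
    tau_trials: float  # learning time-constant in cumulative rewards
    hold_mean_ms: float
    hold_sd_ms: float
    seed: int

    def validate(self) -> None:
        for name in ("engage_prob", "p0_correct", "p_inf_correct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.p_inf_correct < self.p0_correct:
            raise InputError("p_inf_correct must be >= p0_correct")
        if self.tau_trials <= 0:
            raise InputError("tau_trials must be > 0")
        if self.hold_mean_ms <= 0:
            raise InputError("hold_mean_ms must be > 0")
        if self.engage_rate_per_min <= 0:
            raise InputError("engage_rate_per_min must be > 0")


@dataclass
class AgentState:
    """Evolving learning state of one subject."""

    cumulative_rewards: int = 0
    p_correct: float = 0.25
    engaged: bool = False


def learning_curve(r: int, params: AgentParams) -> float:
    """Cue-following probability after ``r`` cumulative rewards."""
    return params.p_inf_correct - (params.p_inf_correct - params.p0_correct) * math.exp(
        -r / params.tau_trials
    )


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    # rejection sampling; bounds are always within a few sd of the mean here
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _subject_entropy(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf-8"))


def make_agent(archetype: Archetype, master_seed: int, subject_id: str) -> AgentParams:
    """Draw a subject's parameters from its archetype distributions.

    Deterministic in ``(master_seed, subject_id)``.
    """
    defaults = calibration.ARCHETYPE_DEFAULTS[archetype.value]
    rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, _subject_entropy(subject_id)])
    )
    params = AgentParams(
        archetype=archetype,
        engage_rate_per_min=_truncnorm(rng, *defaults["engage_rate_per_min"]),
        engage_prob=defaults["engage_prob"],
        p0_correct=defaults["p0_correct"],
        p_inf_correct=_truncnorm(rng, *defaults["p_inf_correct"]),
        tau_trials=_truncnorm(rng, *defaults["tau_trials"]),
        hold_mean_ms=_truncnorm(rng, *defaults["hold_mean_ms"]),
        hold_sd_ms=defaults["hold_sd_ms"],
        seed=int(rng.integers(0, 2**31)),
    )
    params.validate()
    return params


def agent_act(
    params: AgentParams,
    state: AgentState,
    cue_view,
    clock_ms: int,
    rng: np.random.Generator,
    config: TaskConfig,
) -> Optional[PressAttempt]:
    """The agent's next press, or None to wait out the rest of the session.

    The press starts an Exp(rate)-distributed interval after ``clock_ms``;
    the cued button is chosen with probability ``p_correct`` (uniform over
    the other active buttons otherwise); with no visible cue (time-out, or
    the any-button task) the choice is uniform over all active buttons. Hold
    duration is truncated-normal with a 1 ms floor.
    """
    if not state.engaged:
        return None
    gap_ms = rng.exponential(60_000.0 / params.engage_rate_per_min)
    t_down = clock_ms + max(1, int(round(gap_ms)))
    if t_down >= config.session_cap_ms:
        return None
    active = config.task_variant.active_buttons
    if isinstance(cue_view, int) and rng.random() < state.p_correct:
        button = cue_view
    elif isinstance(cue_view, int) and active > 1:
        others = [b for b in range(1, active + 1) if b != cue_view]
        button = others[rng.integers(0, len(others))]
    else:
        button = int(rng.integers(1, active + 1))
    duration = max(1, int(round(rng.normal(params.hold_mean_ms, params.hold_sd_ms))))
    return PressAttempt(button=int(button), t_down_ms=t_down, duration_ms=duration)


def update_agent(state: AgentState, record: TrialRecord, params: AgentParams) -> AgentState:
    """Advance learning state after a scored trial (mutates ``state``).

    Only rewarded trials move the learning curve; errors and time-out presses
    leave it unchanged.
    """
    if record.outcome is Outcome.SUCCESS:
        state.cumulative_rewards += 1
        state.p_correct = learning_curve(state.cumulative_rewards, params)
    return state


def run_agent_session(
    params: AgentParams,
    state: AgentState,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    subject_id: str,
    facility: str,
    session_index: int,
    start: datetime,
    annotation: str = "",
) -> SessionLog:
    """Simulate one closed-loop session: agent vs engine, learning online."""
    engine = init_session(config, start)
    state.engaged = bool(rng.random() < params.engage_prob)
    clock = 0
    while True:
        press = agent_act(params, state, engine.cue_visible, clock, rng, config)
        if press is None:
            break
        _, record = score_press(engine, press, config)
        update_agent(state, record, params)
        clock = press.t_up_ms
    return SessionLog(
        subject_id=subject_id,
        facility=facility,
        session_index=session_index,
        start=start,
        config=config,
        actual_duration_ms=config.session_cap_ms,
        trials=engine.trial_history,
        annotation=annotation,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition, itinerary and seeding of a simulated cohort."""

    n_users: int = calibration.DEFAULT_N_PER_ARCHETYPE["USER"]
    n_non_users: int = calibration.DEFAULT_N_PER_ARCHETYPE["NON_USER"]
    n_unexposed: int = calibration.DEFAULT_N_PER_ARCHETYPE["UNEXPOSED"]
    bf_sessions: int = calibration.DEFAULT_ITINERARY["bf_sessions"]
    rf_sessions: int = calibration.DEFAULT_ITINERARY["rf_sessions"]
    lab_sessions: int = calibration.DEFAULT_ITINERARY["lab_sessions"]
    bf_session_min: int = calibration.DEFAULT_ITINERARY["bf_session_min"]
    rf_session_min: int = calibration.DEFAULT_ITINERARY["rf_session_min"]
    n_buttons: int = 4
    master_seed: int = calibration.DEFAULT_MASTER_SEED
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def validate(self) -> None:
        if self.n_users + self.n_non_users + self.n_unexposed < 1:
            raise InputError("cohort must contain at least one subject")
        if min(self.n_users, self.n_non_users, self.n_unexposed) < 0:
            raise InputError("archetype counts must be >= 0")
        if self.rf_sessions < 1 or self.lab_sessions < 1:
            raise InputError("itinerary must include RF and lab sessions")
        if self.bf_sessions < 0 or self.bf_session_min <= 0 or self.rf_session_min <= 0:
            raise InputError("infeasible itinerary")

    def checksum(self) -> str:
        payload = {
            k: (v if not isinstance(v, ProtocolConfig) else repr(v))
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @property
    def n_subjects(self) -> int:
        return self.n_users + self.n_non_users + self.n_unexposed


@dataclass
class CohortDataset:
    """All subjects' session logs plus subject metadata and provenance."""

    subjects: "object"  # pandas.DataFrame: subject_id, housing_group, archetype, ...
    logs: List[SessionLog]
    provenance: Dict[str, object] = field(default_factory=dict)

    def logs_for(self, subject_id: str, facility: Optional[str] = None) -> List[SessionLog]:
        out = [
            lg
            for lg in self.logs
            if lg.subject_id == subject_id
            and (facility is None or lg.facility == facility)
        ]
        return sorted(out, key=lambda lg: (lg.facility, lg.session_index))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for lg in sorted(self.logs, key=lambda l: (l.subject_id, l.facility, l.session_index)):
            h.update(
                f"{lg.subject_id}|{lg.facility}|{lg.session_index}|"
                f"{lg.successes}|{lg.attempts}|{lg.config.rng_seed}".encode()
            )
            for t in lg.trials:
                h.update(
                    f"{t.press.button},{t.press.t_down_ms},{t.press.duration_ms},"
                    f"{t.cued_button},{t.outcome.value}".encode()
                )
        return h.hexdigest()


_FACILITY_CODE = {"BF": 0, "RF": 1, "LAB": 2}

# Facility start dates (Mondays); sessions run on consecutive working days.
_FACILITY_START = {
    "BF": datetime(2021, 1, 4, 9, 0),
    "RF": datetime(2021, 3, 1, 9, 0),
    "LAB": datetime(2021, 6, 7, 9, 0),
}


def _working_day(start: datetime, k: int) -> datetime:
    """The k-th (0-based) working day on/after ``start`` (a Monday)."""
    weeks, rem = divmod(k, 5)
    return start + timedelta(days=7 * weeks + rem)


def _session_rng(master_seed: int, subject_idx: int, facility: str, index: int, stream: int):
    ss = np.random.SeedSequence(
        [master_seed, subject_idx, _FACILITY_CODE[facility], index, stream]
    )
    return np.random.default_rng(ss)


def _engine_seed(master_seed: int, subject_idx: int, facility: str, index: int) -> int:
    ss = np.random.SeedSequence(
        [master_seed, subject_idx, _FACILITY_CODE[facility], index, 0]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _subject_metadata(rng: np.random.Generator) -> dict:
    return {
        "age_months": int(rng.integers(26, 81)),
        "weight_kg": round(float(rng.uniform(3.3, 7.7)), 2),
        "rank": ["Dom", "Mid", "Sub"][int(rng.integers(0, 3))],
    }


def _housing_groups(n: int) -> List[int]:
    sizes = calibration.DEFAULT_HOUSING_GROUP_SIZES
    groups: List[int] = []
    g = 0
    while len(groups) < n:
        size = sizes[g % len(sizes)]
        groups.extend([g + 1] * size)
        g += 1
    return groups[:n]


def _facility_block(
    subject_idx: int,
    subject_id: str,
    params: AgentParams,
    state: AgentState,
    facility: str,
    n_sessions: int,
    spec: CohortSpec,
    incoming_stage: Optional[TaskVariant],
) -> Tuple[List[SessionLog], TaskVariant]:
    """Run one subject through all sessions at one facility."""
    history: Dict[TaskVariant, List[SessionLog]] = {}
    logs: List[SessionLog] = []
    last_stage = incoming_stage or TaskVariant.ONE_BUTTON
    for k in range(1, n_sessions + 1):
        stage = next_task_stage(
            history, facility, spec.protocol, incoming_stage=incoming_stage
        )
        if facility == "LAB":
            cap_min = lab_session_cap(k, spec.protocol)
        elif facility == "BF":
            cap_min = spec.bf_session_min
        else:
            cap_min = spec.rf_session_min
        config = TaskConfig(
            task_variant=stage,
            n_buttons=spec.n_buttons,
            session_cap_ms=cap_min * 60_000,
            rng_seed=_engine_seed(spec.master_seed, subject_idx, facility, k),
        )
        rng = _session_rng(spec.master_seed, subject_idx, facility, k, stream=1)
        log = run_agent_session(
            params,
            state,
            config,
            rng,
            subject_id=subject_id,
            facility=facility,
            session_index=k,
            start=_working_day(_FACILITY_START[facility], k - 1),
        )
        logs.append(log)
        history.setdefault(stage, []).append(log)
        last_stage = stage
    return logs, last_stage


def simulate_cohort(spec: Optional[CohortSpec] = None) -> CohortDataset:
    """Simulate the full cohort through BF, RF and lab itineraries.

    UNEXPOSED subjects skip the breeding facility entirely. Within RF and lab,
    stage progression is evaluated after every session. Fully reproducible
    from ``spec.master_seed``.
    """
    import pandas as pd

    spec = spec or CohortSpec()
    spec.validate()

    archetypes = (
        [Archetype.USER] * spec.n_users
        + [Archetype.NON_USER] * spec.n_non_users
        + [Archetype.UNEXPOSED] * spec.n_unexposed
    )
    groups = _housing_groups(len(archetypes))
    rows = []
    logs: List[SessionLog] = []
    for idx, archetype in enumerate(archetypes):
        subject_id = f"S{idx + 1:02d}"
        params = make_agent(archetype, spec.master_seed, subject_id)
        state = AgentState(p_correct=params.p0_correct)
        meta_rng = np.random.default_rng(
            np.random.SeedSequence([spec.master_seed, idx, 99])
        )
        rows.append(
            {
                "subject_id": subject_id,
                "housing_group": groups[idx],
                "archetype": archetype.value,
                **_subject_metadata(meta_rng),
            }
        )
        last_stage: Optional[TaskVariant] = None
        if archetype is not Archetype.UNEXPOSED and spec.bf_sessions > 0:
            bf_logs, last_stage = _facility_block(
                idx, subject_id, params, state, "BF", spec.bf_sessions, spec, None
            )
            logs.extend(bf_logs)
        rf_logs, _ = _facility_block(
            idx, subject_id, params, state, "RF", spec.rf_sessions, spec, last_stage
        )
        logs.extend(rf_logs)
        lab_logs, _ = _facility_block(
            idx, subject_id, params, state, "LAB", spec.lab_sessions, spec, None
        )
        logs.extend(lab_logs)

    return CohortDataset(
        subjects=pd.DataFrame(rows),
        logs=logs,
        provenance={"master_seed": spec.master_seed, "spec_checksum": spec.checksum()},
    )
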