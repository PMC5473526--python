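"""Performance measures, subject classification, analysis windows and the
group-comparison statistics.

Per-session performance is measured two ways: the rate of successful presses
per hour of session time (``cp_per_hr``) and the percentage of all recorded
press attempts that were successful (``pct_correct``). Subjects are
classified from their breeding-facility logs as USER (>= 30 successful
presses in at least one session), NON_USER (exposed but never reached that
mark) or UNEXPOSED (no breeding-facility sessions at all). Group comparisons
treat each subject as one independent observation: a subject's sessions are
averaged first, group mean and standard error are then taken over subjects,
and groups are compared with non-parametric rank tests (exact Mann-Whitney by
full enumeration where feasible, Kruskal-Wallis with tie correction) plus
ordinary least-squares regression for practice-vs-performance questions.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .subject_sim import Archetype, CohortDataset
from .task_engine import InputError, Outcome, SessionLog, TaskVariant

__all__ = [
    "BUILTIN_WINDOWS",
    "ClassificationRule",
    "GroupComparison",
    "Measure",
    "NOT_REACHED",
    "SessionMetrics",
    "WindowAnchor",
    "WindowSpec",
    "classify_bf",
    "group_summary",
    "kruskal_wallis",
    "mann_whitney_exact",
    "ols_regression",
    "select_window",
    "session_metrics",
    "sessions_to_criterion",
]

#: Sentinel returned when a subject never meets the performance criterion.
NOT_REACHED = None

#: Enumeration is exact up to this many group assignments; beyond it the
#: Mann-Whitney p-value switches to a tie-corrected normal approximation.
_EXACT_ENUMERATION_LIMIT = 1_000_000


class Measure(enum.Enum):
    CP_HR = "cp_hr"  # successful presses per hour
    PCT = "pct"  # percent of attempts successful


@dataclass(frozen=True)
class SessionMetrics:
    """Per-session summary: counts plus the two headline rates.

    ``pct_correct`` is None (undefined, not zero) for a session with no
    presses at all.
    """

    successes: int
    attempts: int
    cp_per_hr: float
    pct_correct: Optional[float]


def session_metrics(log: SessionLog, *, include_timeout_presses: bool = True) -> SessionMetrics:
    """Compute both performance measures for one session.

    ``attempts`` counts every recorded press regardless of outcome. By
    default time-out presses stay in the percent-correct denominator (they
    are recorded presses); set ``include_timeout_presses=False`` to restrict
    the denominator to presses scored against a lit cue.
    """
    attempts = log.attempts
    successes = log.successes
    hours = log.actual_duration_ms / 3_600_000
    denom = attempts
    if not include_timeout_presses:
        denom -= sum(1 for t in log.trials if t.outcome is Outcome.TIMEOUT_PRESS)
    pct = 100.0 * successes / denom if denom > 0 else None
    return SessionMetrics(
        successes=successes,
        attempts=attempts,
        cp_per_hr=successes / hours if hours > 0 else 0.0,
        pct_correct=pct,
    )


@dataclass(frozen=True)
class ClassificationRule:
    """USER label requires this many successes in at least one BF session."""

    user_min_successes: int = 30

    def validate(self) -> None:
        if self.user_min_successes < 1:
            raise InputError("user_min_successes must be >= 1")


def classify_bf(
    subject_logs: Sequence[SessionLog],
    rule: Optional[ClassificationRule] = None,
) -> Archetype:
    """Classify a subject from its breeding-facility session logs.

    No BF logs at all -> UNEXPOSED; any single session with at least
    ``rule.user_min_successes`` successes -> USER; otherwise NON_USER.
    """
    rule = rule or ClassificationRule()
    rule.validate()
    if any(lg.facility != "BF" for lg in subject_logs):
        raise InputError("classify_bf expects breeding-facility logs only")
    if not subject_logs:
        return Archetype.UNEXPOSED
    if any(lg.successes >= rule.user_min_successes for lg in subject_logs):
        return Archetype.USER
    return Archetype.NON_USER


def sessions_to_criterion(
    subject_logs: Sequence[SessionLog], threshold: int = 100
) -> Optional[int]:
    """1-based index of the first session with >= threshold successes.

    Sessions are taken in the given order regardless of task variant.
    Returns ``NOT_REACHED`` (None) if the criterion is never met.
    """
    for i, lg in enumerate(subject_logs, start=1):
        if lg.successes >= threshold:
            return i
    return NOT_REACHED


class WindowAnchor(enum.Enum):
    ARRIVAL = "ARRIVAL"  # session index counted from facility arrival
    STAGE_ONSET = "STAGE_ONSET"  # counted from the first session of a stage
    LAB_ONSET = "LAB_ONSET"  # alias of ARRIVAL for the laboratory


@dataclass(frozen=True)
class WindowSpec:
    """An inclusive, 1-based slice of a subject's sessions at one facility."""

    name: str
    facility: str
    anchor: WindowAnchor
    first_index: int
    last_index: int
    stage: Optional[TaskVariant] = None  # required for STAGE_ONSET

    def validate(self) -> None:
        if self.first_index > self.last_index:
            raise InputError("first_index must be <= last_index")
        if self.first_index < 1:
            raise InputError("window indices are 1-based")
        if self.anchor is WindowAnchor.STAGE_ONSET and self.stage is None:
            raise InputError("STAGE_ONSET window needs a stage")


BUILTIN_WINDOWS: Dict[str, WindowSpec] = {
    # Research-facility sessions 5-27 post arrival (first 4 discarded).
    "rf_main": WindowSpec("rf_main", "RF", WindowAnchor.ARRIVAL, 5, 27),
    # First 13 sessions after a subject moves to the 4-button task.
    "rf_4b": WindowSpec(
        "rf_4b", "RF", WindowAnchor.STAGE_ONSET, 1, 13, stage=TaskVariant.FOUR_BUTTON
    ),
    # Early research-facility sessions 5-12 (practice-matched to the lab window).
    "rf_early": WindowSpec("rf_early", "RF", WindowAnchor.ARRIVAL, 5, 12),
    # First 8 laboratory sessions.
    "lab_early": WindowSpec("lab_early", "LAB", WindowAnchor.LAB_ONSET, 1, 8),
}


def select_window(subject_logs: Sequence[SessionLog], spec: WindowSpec) -> List[SessionLog]:
    """Subset one subject's logs to the window, ordered by session index.

    Raises InputError when the anchor event is absent (no sessions at the
    facility, or the anchoring stage was never reached). Sessions missing at
    the tail of the window are simply not returned.
    """
    spec.validate()
    logs = sorted(
        (lg for lg in subject_logs if lg.facility == spec.facility),
        key=lambda lg: lg.session_index,
    )
    if not logs:
        raise InputError(f"no {spec.facility} sessions: window anchor absent")
    if spec.anchor is WindowAnchor.STAGE_ONSET:
        onset = next(
            (lg.session_index for lg in logs if lg.config.task_variant is spec.stage),
            None,
        )
        if onset is None:
            raise InputError(
                f"subject never reached stage {spec.stage}: window anchor absent"
            )
        offset = onset - 1
    else:
        offset = 0
    lo = offset + spec.first_index
    hi = offset + spec.last_index
    return [lg for lg in logs if lo <= lg.session_index <= hi]


@dataclass
class GroupComparison:
    """Group means/SEs over subjects, per-session learning curves and tests.

    ``group_stats`` has one row per group (mean, se, n); SE is computed over
    subjects (each animal one independent observation) and is NaN for n=1.
    ``learning_curves`` has one row per (group, relative session index).
    """

    window: str
    measure: Measure
    group_stats: pd.DataFrame
    learning_curves: pd.DataFrame
    kruskal: Optional[Tuple[float, float]]
    mann_whitney_user_vs_nonuser: Optional[Tuple[float, float]]
    subject_means: pd.DataFrame


def _measure_value(log: SessionLog, measure: Measure) -> Optional[float]:
    m = session_metrics(log)
    return m.cp_per_hr if measure is Measure.CP_HR else m.pct_correct


def group_summary(
    cohort: CohortDataset,
    window: WindowSpec,
    measure: Measure = Measure.CP_HR,
    rule: Optional[ClassificationRule] = None,
) -> GroupComparison:
    """Compare classification groups on one measure over one window.

    Subjects are classified from their BF logs. For each subject the measure
    is averaged across the window's sessions (sessions with an undefined
    percentage are skipped); group mean +/- SE is then taken across subjects.
    Empty groups are omitted with a warning. Also returns per-session group
    learning curves and the Kruskal-Wallis / exact Mann-Whitney
    (Users vs Non-users) tests on the subject means.
    """
    subject_ids = list(cohort.subjects["subject_id"].astype(str))
    rows = []
    curve_rows = []
    for sid in subject_ids:
        group = classify_bf(cohort.logs_for(sid, "BF"), rule)
        try:
            logs = select_window(cohort.logs_for(sid, window.facility), window)
        except InputError:
            continue  # anchor absent for this subject: no window data
        values = [
            (lg.session_index, v)
            for lg in logs
            if (v := _measure_value(lg, measure)) is not None
        ]
        if not values:
            continue
        rows.append(
            {
                "subject_id": sid,
                "group": group.value,
                "mean": float(np.mean([v for _, v in values])),
                "n_sessions": len(values),
            }
        )
        base = min(idx for idx, _ in values)
        for idx, v in values:
            curve_rows.append(
                {
                    "subject_id": sid,
                    "group": group.value,
                    "session": idx - base + window.first_index,
                    "value": v,
                }
            )

    subject_means = pd.DataFrame(rows)
    if subject_means.empty:
        raise InputError(f"no data in window {window.name}")

    stats_rows = []
    for group_name in [a.value for a in Archetype]:
        vals = subject_means.loc[subject_means["group"] == group_name, "mean"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"group {group_name} empty in window {window.name}; omitted")
            continue
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        stats_rows.append(
            {"group": group_name, "mean": float(np.mean(vals)), "se": se, "n": len(vals)}
        )
    group_stats = pd.DataFrame(stats_rows).set_index("group")

    curves = (
        pd.DataFrame(curve_rows)
        .groupby(["group", "session"], as_index=False)["value"]
        .mean()
        if curve_rows
        else pd.DataFrame(columns=["group", "session", "value"])
    )

    groups_present = [
        subject_means.loc[subject_means["group"] == g, "mean"].to_numpy()
        for g in group_stats.index
    ]
    kw = kruskal_wallis(groups_present) if len(groups_present) >= 2 else None
    mw = None
    u_vals = subject_means.loc[subject_means["group"] == "USER", "mean"].to_numpy()
    n_vals = subject_means.loc[subject_means["group"] == "NON_USER", "mean"].to_numpy()
    if len(u_vals) >= 1 and len(n_vals) >= 1:
        mw = mann_whitney_exact(u_vals, n_vals)

    return GroupComparison(
        window=window.name,
        measure=measure,
        group_stats=group_stats,
        learning_curves=curves,
        kruskal=kw,
        mann_whitney_user_vs_nonuser=mw,
        subject_means=subject_means,
    )


def _u_statistics(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(U_x, U_y) from mid-ranks of the pooled sample."""
    n_x, n_y = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2)
    return u_x, n_x * n_y - u_x


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U with an exact two-sided p for small samples.

    U is reported as min(U_x, U_y) with mid-rank ties. The p-value is the
    permutation-null probability P(min(U_x, U_y) <= observed), computed by
    full enumeration of all C(n_x+n_y, n_x) group assignments of the pooled
    mid-ranks whenever that count is at most 10^6; larger samples use a
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 1 or n_y < 1:
        raise InputError("both samples must be non-empty")
    u_x, u_y = _u_statistics(x, y)
    u_obs = min(u_x, u_y)

    n = n_x + n_y
    if math.comb(n, n_x) <= _EXACT_ENUMERATION_LIMIT:
        ranks = stats.rankdata(np.concatenate([x, y]))
        total_rank = ranks.sum()
        hits = 0
        total = 0
        # enumeration is over which pooled positions form the x-group
        for combo in itertools.combinations(range(n), n_x):
            rx = sum(ranks[i] for i in combo)
            ux = rx - n_x * (n_x + 1) / 2
            if min(ux, n_x * n_y - ux) <= u_obs + 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = n_x * n_y / 2
    sigma2 = n_x * n_y / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu + 0.5) / math.sqrt(sigma2)
    return u_obs, float(min(1.0, 2 * stats.norm.cdf(z)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df.

    The chi-square reference is an approximation that is anti-conservative
    for very small groups; the study-scale group sizes (3-8 subjects) sit at
    the edge of its validity, which is why the exact Mann-Whitney test backs
    up pairwise contrasts.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise InputError("kruskal_wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    pos = 0
    for a in arrays:
        r = ranks[pos : pos + a.size]
        h += a.size * (r.mean() - (n + 1) / 2) ** 2
        pos += a.size
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_correction = 1 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie_correction == 0:  # every value identical
        return 0.0, 1.0
    h /= tie_correction
    p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    return float(h), p


def ols_regression(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float, float]:
    """Least-squares line fit: (slope, intercept, R^2, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("regression needs n >= 3 paired observations")
    if np.all(x == x[0]):
        raise InputError("x must not be constant")
    if np.allclose(y, y[0]):
        # a flat response is fit exactly by a horizontal line
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )
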