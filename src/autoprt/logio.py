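"""Canonical on-disk session-log format, validation and cohort bundles.

A session log is a UTF-8 CSV file: header metadata as ``#key=value`` lines
(session identity plus a full echo of the task parameters), a column-header
row, then one row per scored press::

    #subject_id=S01
    #facility=RF
    #session_index=5
    ...
    timestamp,cued_button,pressed_button,t_down_ms,duration_ms,outcome,reward
    2021-03-05T09:00:12.345000,2,2,12345,180,SUCCESS,true

A cohort bundle is a directory of ``<subject>_<facility>_<index>.csv`` log
files plus a ``subjects.csv`` table (id, housing group, age, weight, rank).
The reader validates every invariant and never silently coerces: malformed
rows raise with a line number, and per-subject per-facility session indices
must be contiguous from 1.
"""

from __future__ import annotations

import csv
import io
import os
from datetime import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

from .subject_sim import CohortDataset
from .task_engine import (
    ANY,
    Outcome,
    PressAttempt,
    SessionLog,
    TaskConfig,
    TaskVariant,
    TimeoutPolicy,
    TrialRecord,
)

__all__ = [
    "CohortError",
    "LogFormatError",
    "LogValidationError",
    "log_filename",
    "merge_cohort",
    "read_session_log",
    "validate_session_log",
    "write_cohort",
    "write_session_log",
]

COLUMNS = (
    "timestamp",
    "cued_button",
    "pressed_button",
    "t_down_ms",
    "duration_ms",
    "outcome",
    "reward",
)

_CONFIG_KEYS = (
    "task_variant",
    "n_buttons",
    "hold_time_ms",
    "timeout_ms",
    "timeout_prolong",
    "session_cap_ms",
    "reward_units_per_success",
    "refractory_ms",
    "rng_seed",
)

_HEADER_KEYS = (
    "subject_id",
    "facility",
    "session_index",
    "datetime",
    *_CONFIG_KEYS,
    "actual_duration_ms",
    "annotation",
)

FACILITIES = ("BF", "RF", "LAB")


class LogFormatError(ValueError):
    """Malformed file: missing header, bad row, unknown token."""


class LogValidationError(ValueError):
    """Well-formed file whose content violates a session-log invariant."""


class CohortError(ValueError):
    """Inconsistent cohort bundle (orphans, duplicates, gaps)."""


def validate_session_log(log: SessionLog) -> None:
    """Raise LogValidationError unless the log satisfies all invariants."""
    if log.session_index < 1:
        raise LogValidationError("session_index must be >= 1")
    if log.facility not in FACILITIES:
        raise LogValidationError(f"facility must be one of {FACILITIES}")
    if log.actual_duration_ms > log.config.session_cap_ms:
        raise LogValidationError(
            f"actual_duration_ms {log.actual_duration_ms} exceeds the session "
            f"cap {log.config.session_cap_ms}"
        )
    if log.actual_duration_ms <= 0:
        raise LogValidationError("actual_duration_ms must be > 0")
    prev = -1
    for i, t in enumerate(log.trials):
        if t.press.t_down_ms < prev:
            raise LogValidationError(f"trial {i}: t_down_ms decreases")
        if t.press.t_down_ms >= log.actual_duration_ms:
            raise LogValidationError(
                f"trial {i}: press at {t.press.t_down_ms} ms is outside the "
                f"session duration {log.actual_duration_ms} ms"
            )
        prev = t.press.t_down_ms


def _cue_token(cue) -> str:
    return ANY if cue == ANY else str(int(cue))


def write_session_log(log: SessionLog, sink: Union[str, Path, io.TextIOBase]) -> None:
    """Write a validated log to a path or text stream in the canonical CSV dialect."""
    validate_session_log(log)
    own = isinstance(sink, (str, Path, os.PathLike))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        cfg = log.config
        header = {
            "subject_id": log.subject_id,
            "facility": log.facility,
            "session_index": log.session_index,
            "datetime": log.start.isoformat(),
            "task_variant": cfg.task_variant.name,
            "n_buttons": cfg.n_buttons,
            "hold_time_ms": cfg.hold_time_ms,
            "timeout_ms": cfg.timeout_ms,
            "timeout_prolong": cfg.timeout_prolong.name,
            "session_cap_ms": cfg.session_cap_ms,
            "reward_units_per_success": cfg.reward_units_per_success,
            "refractory_ms": cfg.refractory_ms,
            "rng_seed": cfg.rng_seed,
            "actual_duration_ms": log.actual_duration_ms,
            "annotation": log.annotation.replace("\n", " "),
        }
        for key in _HEADER_KEYS:
            fh.write(f"#{key}={header[key]}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for t in log.trials:
            writer.writerow(
                [
                    t.timestamp.isoformat(),
                    _cue_token(t.cued_button),
                    t.press.button,
                    t.press.t_down_ms,
                    t.press.duration_ms,
                    t.outcome.value,
                    "true" if t.reward else "false",
                ]
            )
    finally:
        if own:
            fh.close()


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise LogFormatError(f"line {lineno}: {what} {token!r} is not an integer") from None


def read_session_log(source: Union[str, Path, io.TextIOBase]) -> SessionLog:
    """Parse and validate a session log; unknown ``#`` keys are kept in the annotation."""
    own = isinstance(source, (str, Path, os.PathLike))
    fh = open(source, "r", encoding="utf-8", newline="") if own else source
    try:
        header: Dict[str, str] = {}
        extra: List[str] = []
        lineno = 0
        line = fh.readline()
        while line.startswith("#"):
            lineno += 1
            body = line[1:].rstrip("\n")
            key, sep, value = body.partition("=")
            if not sep:
                raise LogFormatError(f"line {lineno}: header line without '='")
            if key in _HEADER_KEYS:
                header[key] = value
            else:
                extra.append(f"{key}={value}")
            line = fh.readline()
        lineno += 1
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise LogFormatError(f"missing header keys: {', '.join(missing)}")
        if line.rstrip("\n").split(",") != list(COLUMNS):
            raise LogFormatError(f"line {lineno}: expected column header {','.join(COLUMNS)}")

        try:
            config = TaskConfig(
                task_variant=TaskVariant[header["task_variant"]],
                n_buttons=int(header["n_buttons"]),
                hold_time_ms=int(header["hold_time_ms"]),
                timeout_ms=int(header["timeout_ms"]),
                timeout_prolong=TimeoutPolicy[header["timeout_prolong"]],
                session_cap_ms=int(header["session_cap_ms"]),
                reward_units_per_success=float(header["reward_units_per_success"]),
                refractory_ms=int(header["refractory_ms"]),
                rng_seed=int(header["rng_seed"]),
            )
            start = datetime.fromisoformat(header["datetime"])
            session_index = int(header["session_index"])
        except (KeyError, ValueError) as exc:
            raise LogFormatError(f"bad header value: {exc}") from None

        trials: List[TrialRecord] = []
        for row in csv.reader(fh):
            lineno += 1
            if not row:  # tolerate trailing blank line(s)
                continue
            if len(row) != len(COLUMNS):
                raise LogFormatError(
                    f"line {lineno}: expected {len(COLUMNS)} fields, got {len(row)}"
                )
            ts_tok, cue_tok, btn_tok, down_tok, dur_tok, out_tok, rew_tok = row
            try:
                timestamp = datetime.fromisoformat(ts_tok)
            except ValueError:
                raise LogFormatError(f"line {lineno}: bad timestamp {ts_tok!r}") from None
            cued = ANY if cue_tok == ANY else _parse_int(cue_tok, "cued_button", lineno)
            try:
                outcome = Outcome(out_tok)
            except ValueError:
                raise LogFormatError(f"line {lineno}: unknown outcome {out_tok!r}") from None
            if rew_tok not in ("true", "false"):
                raise LogFormatError(f"line {lineno}: reward must be true/false, got {rew_tok!r}")
            reward = rew_tok == "true"
            if reward != (outcome is Outcome.SUCCESS):
                raise LogValidationError(
                    f"line {lineno}: reward flag inconsistent with outcome {out_tok}"
                )
            trials.append(
                TrialRecord(
                    press=PressAttempt(
                        button=_parse_int(btn_tok, "pressed_button", lineno),
                        t_down_ms=_parse_int(down_tok, "t_down_ms", lineno),
                        duration_ms=_parse_int(dur_tok, "duration_ms", lineno),
                    ),
                    cued_button=cued,
                    outcome=outcome,
                    reward=reward,
                    timestamp=timestamp,
                )
            )

        annotation = header["annotation"]
        if extra:
            annotation = "; ".join(filter(None, [annotation, *extra]))
        log = SessionLog(
            subject_id=header["subject_id"],
            facility=header["facility"],
            session_index=session_index,
            start=start,
            config=config,
            actual_duration_ms=int(header["actual_duration_ms"]),
            trials=trials,
            annotation=annotation,
        )
        validate_session_log(log)
        return log
    finally:
        if own:
            fh.close()


def log_filename(log: SessionLog) -> str:
    return f"{log.subject_id}_{log.facility}_{log.session_index}.csv"


def merge_cohort(
    log_files: Iterable[Union[str, Path, SessionLog]],
    subject_table,
) -> CohortDataset:
    """Assemble session logs and a subject table into a verified CohortDataset.

    ``subject_table`` is a pandas DataFrame with at least a ``subject_id``
    column (the shape of ``subjects.csv``). Orphan subject ids, duplicate
    (subject, facility, index) triples and index gaps are all rejected.
    """
    logs: List[SessionLog] = []
    for item in log_files:
        logs.append(item if isinstance(item, SessionLog) else read_session_log(item))

    known = set(subject_table["subject_id"].astype(str))
    orphans = sorted({lg.subject_id for lg in logs} - known)
    if orphans:
        raise CohortError(f"logs reference unknown subject ids: {', '.join(orphans)}")

    seen: Dict[tuple, SessionLog] = {}
    for lg in logs:
        key = (lg.subject_id, lg.facility, lg.session_index)
        if key in seen:
            raise CohortError(f"duplicate session {key}")
        seen[key] = lg
    by_sf: Dict[tuple, List[int]] = {}
    for subject_id, facility, index in seen:
        by_sf.setdefault((subject_id, facility), []).append(index)
    for (subject_id, facility), indices in by_sf.items():
        indices.sort()
        if indices != list(range(1, len(indices) + 1)):
            raise CohortError(
                f"{subject_id}/{facility}: session indices {indices} are not "
                f"contiguous from 1"
            )

    return CohortDataset(subjects=subject_table.reset_index(drop=True), logs=logs)


def write_cohort(dataset: CohortDataset, out_dir: Union[str, Path]) -> Path:
    """Write a cohort bundle: one CSV per log plus ``subjects.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.subjects.to_csv(out / "subjects.csv", index=False)
    for lg in dataset.logs:
        write_session_log(lg, out / log_filename(lg))
    return out


def read_cohort(in_dir: Union[str, Path]) -> CohortDataset:
    """Read a cohort bundle written by :func:`write_cohort`."""
    import pandas as pd

    root = Path(in_dir)
    subjects_path = root / "subjects.csv"
    if not subjects_path.exists():
        raise CohortError(f"no subjects.csv in {root}")
    log_paths = sorted(p for p in root.glob("*.csv") if p.name != "subjects.csv")
    if not log_paths:
        raise CohortError(f"no session logs found in {root}")
    return merge_cohort(log_paths, pd.read_csv(subjects_path))
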