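"""Session file format, validation, and quality-control filters.

A session file is UTF-8 JSONL with one record per trial::

    {"participant_id": ..., "age_mo": ..., "sex": ..., "device": ...,
     "task": ..., "trial_index": ..., "block": ..., "rotation_deg": ...,
     "clamp": ..., "clamp_jitter_deg": ...,
     "events": {"t_trial_start_ms": ..., "t_click_ms": ...},
     "samples": [[t_ms, x_gu, y_gu], ...]}

Numeric fields are written with at most 6 fractional digits so a
write/read cycle is lossless.  Files ending in ``.gz`` are transparently
gzip-compressed.

Quality control mirrors the study's data review: participants are
excluded for sessions longer than a duration cap, median input-device
polling rates below a floor (polling is only observable while the hand
moves), or incomplete sessions.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .kinematics import Trajectory
from .paradigm import BLOCK_LENGTHS, TrialSpec

__all__ = [
    "TrialRecord",
    "Session",
    "SessionFormatError",
    "read_sessions",
    "write_sessions",
    "QCPolicy",
    "apply_qc",
    "session_duration_min",
    "median_polling_hz",
]

log = logging.getLogger(__name__)

_REQUIRED_KEYS = {
    "participant_id",
    "age_mo",
    "sex",
    "device",
    "task",
    "trial_index",
    "block",
    "rotation_deg",
    "clamp",
    "events",
    "samples",
}


class SessionFormatError(ValueError):
    """A session file violates the JSONL schema or a trajectory invariant."""


@dataclass
class TrialRecord:
    spec: TrialSpec
    trajectory: Trajectory


@dataclass
class Session:
    """All trials of one participant plus constant metadata."""

    participant_id: str
    age_mo: float
    sex: str
    device: str
    task: str
    trials: list[TrialRecord] = field(default_factory=list)


def _round6(x: float) -> float:
    return round(float(x), 6)


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def write_sessions(sessions: Iterable[Session], path) -> None:
    """Serialize sessions to JSONL, one line per trial."""
    with _open(path, "w") as fh:
        for s in sessions:
            for rec in s.trials:
                t = rec.spec
                traj = rec.trajectory
                payload = {
                    "participant_id": s.participant_id,
                    "age_mo": _round6(s.age_mo),
                    "sex": s.sex,
                    "device": s.device,
                    "task": s.task,
                    "trial_index": t.trial_index,
                    "block": t.block,
                    "rotation_deg": _round6(t.rotation_deg),
                    "clamp": t.clamp,
                    "clamp_jitter_deg": None if t.clamp_jitter_deg is None else _round6(t.clamp_jitter_deg),
                    "events": {
                        "t_trial_start_ms": _round6(traj.t_trial_start_ms),
                        "t_click_ms": None if traj.t_click_ms is None else _round6(traj.t_click_ms),
                    },
                    "samples": [
                        [_round6(a), _round6(b), _round6(c)] for a, b, c in traj.samples
                    ],
                }
                fh.write(json.dumps(payload, separators=(",", ":")) + "\n")


def _parse_record(obj: dict, lineno: int) -> tuple[str, dict, TrialRecord]:
    missing = _REQUIRED_KEYS - obj.keys()
    if missing:
        raise SessionFormatError(
            f"line {lineno}: missing field(s) {sorted(missing)}"
        )
    try:
        spec = TrialSpec(
            trial_index=int(obj["trial_index"]),
            block=obj["block"],
            rotation_deg=float(obj["rotation_deg"]),
            clamp=bool(obj["clamp"]),
            clamp_jitter_deg=(
                None if obj.get("clamp_jitter_deg") is None else float(obj["clamp_jitter_deg"])
            ),
        )
    except (TypeError, ValueError) as err:
        raise SessionFormatError(f"line {lineno}: invalid trial spec: {err}") from err
    events = obj["events"]
    try:
        traj = Trajectory(
            samples=np.asarray(obj["samples"], dtype=float),
            t_trial_start_ms=float(events.get("t_trial_start_ms", 0.0)),
            t_click_ms=(
                None if events.get("t_click_ms") is None else float(events["t_click_ms"])
            ),
        )
    except (TypeError, ValueError) as err:
        raise SessionFormatError(
            f"line {lineno} (trial {obj['trial_index']}): invalid trajectory: {err}"
        ) from err
    meta = {
        "participant_id": str(obj["participant_id"]),
        "age_mo": float(obj["age_mo"]),
        "sex": str(obj["sex"]),
        "device": str(obj["device"]),
        "task": str(obj["task"]),
    }
    return meta["participant_id"], meta, TrialRecord(spec=spec, trajectory=traj)


def read_sessions(path) -> list[Session]:
    """Read and validate a session JSONL file.

    Records sharing a participant_id are grouped into one Session (they
    must be contiguous and carry constant metadata).  Malformed lines and
    invariant violations raise :class:`SessionFormatError` naming the
    offending line.
    """
    sessions: list[Session] = []
    by_id: dict[str, Session] = {}
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise SessionFormatError(f"line {lineno}: malformed JSON: {err}") from err
            pid, meta, rec = _parse_record(obj, lineno)
            if pid not in by_id:
                sess = Session(**meta)
                by_id[pid] = sess
                sessions.append(sess)
            else:
                sess = by_id[pid]
                for key in ("age_mo", "sex", "device", "task"):
                    if getattr(sess, key) != meta[key]:
                        raise SessionFormatError(
                            f"line {lineno}: field {key!r} changed within participant {pid}"
                        )
            by_id[pid].trials.append(rec)
    if not sessions:
        log.warning("session file %s is empty", path)
    return sessions


def session_duration_min(session: Session) -> float:
    """Total active game time in minutes (sum of per-trial clocks)."""
    total_ms = sum(float(rec.trajectory.t_ms[-1]) for rec in session.trials)
    return total_ms / 60000.0


def median_polling_hz(session: Session) -> float:
    """Median polling rate over inter-sample intervals during movement.

    Stationary periods produce no polls, so only intervals between
    successive movement samples (after the click sample) enter the
    median.
    """
    dts = []
    for rec in session.trials:
        t = rec.trajectory.t_ms
        if t.size > 2:
            dts.append(np.diff(t[1:]))
    if not dts:
        return 0.0
    all_dt = np.concatenate(dts)
    all_dt = all_dt[all_dt > 0]
    if all_dt.size == 0:
        return 0.0
    return float(np.median(1000.0 / all_dt))


@dataclass
class QCPolicy:
    """Exclusion thresholds mirroring the study's data review."""

    max_session_minutes: float = 120.0
    min_median_polling_hz: float = 20.0
    completion_required: bool = True

    def __post_init__(self) -> None:
        if self.max_session_minutes <= 0 or self.min_median_polling_hz <= 0:
            raise ValueError("QC thresholds must be positive")


def apply_qc(sessions: Iterable[Session], policy: QCPolicy) -> tuple[list[Session], list[dict]]:
    """Split sessions into kept and excluded; each exclusion names its rule."""
    kept: list[Session] = []
    report: list[dict] = []
    for s in sessions:
        reasons = []
        dur = session_duration_min(s)
        if dur > policy.max_session_minutes:
            reasons.append(f"duration {dur:.1f} min exceeds {policy.max_session_minutes:.0f} min cap")
        hz = median_polling_hz(s)
        if hz < policy.min_median_polling_hz:
            reasons.append(
                f"median polling {hz:.1f} Hz below {policy.min_median_polling_hz:.0f} Hz floor"
            )
        if policy.completion_required:
            expected = sum(BLOCK_LENGTHS[s.task].values()) if s.task in BLOCK_LENGTHS else None
            if expected is not None and len(s.trials) != expected:
                reasons.append(
                    f"incomplete session: {len(s.trials)} of {expected} trials"
                )
        if reasons:
            report.append({"participant_id": s.participant_id, "reasons": reasons})
            log.info("QC excluded %s: %s", s.participant_id, "; ".join(reasons))
        else:
            kept.append(s)
    log.info("QC kept %d of %d participants", len(kept), len(kept) + len(report))
    return kept, report
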