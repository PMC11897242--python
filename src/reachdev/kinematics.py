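"""Per-trial kinematic measures from raw hand trajectories.

A trajectory is the sequence of polled input-device positions for one
trial, in hand space (the recorded, un-rotated movement).  The *movement
angle* of a sample is the signed angle between the start-to-sample chord
and the start-to-target ray (0 degrees, counterclockwise positive,
clockwise negative).  From it we derive:

* initial angle (IA): movement angle at the first sample at least 1.2 GU
  (5% of the target distance) from the start — the feedforward,
  adaptation-driven launch direction;
* final angle (FA): movement angle of the last sample — overall
  performance;
* compensation angle: FA - IA — the within-movement, feedback-driven
  correction;
* launch angle: identical computation to FA (the Launch ball reading of
  the start-to-end chord);
* path length ratio: polyline length over start-to-end distance (1 for a
  straight path);
* correction point / normalized correction time: first sample after the
  IA sample whose movement angle leaves the IA +/- 5 degree window, timed
  as a fraction of movement time;
* angle spread: max minus min movement angle from the IA sample to the
  end;
* reaction / stationary / movement times from the trial event times.

Trials whose trajectory never reaches the IA threshold or ends at the
origin are flagged invalid and excluded downstream with a logged reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigm import Schedule, TrialSpec, displayed_angle, evaluate_trial

__all__ = [
    "Trajectory",
    "TrialMeasures",
    "InvalidTrialError",
    "movement_angle",
    "initial_angle",
    "final_angle",
    "compensation_angle",
    "launch_angle",
    "path_length_ratio",
    "correction_metrics",
    "angle_spread",
    "timing_measures",
    "compute_trial_measures",
    "session_measures",
    "measures_table",
    "MEASURES_COLUMNS",
]

log = logging.getLogger(__name__)

IA_THRESHOLD_GU = 1.2
CORRECTION_WINDOW_DEG = 5.0


class InvalidTrialError(ValueError):
    """A trajectory violates a precondition of a measure (degenerate trial)."""


@dataclass
class Trajectory:
    """Timestamped hand-space samples for one trial plus event times.

    ``samples`` is an (n, 3) array of (t_ms, x_gu, y_gu); timestamps are
    strictly increasing and the first sample is at the origin (the
    position reported when the ball is clicked).
    """

    samples: np.ndarray
    t_trial_start_ms: float = 0.0
    t_click_ms: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t_ms, x_gu, y_gu)")
        if self.samples.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValueError("sample timestamps must be strictly increasing")
        if not (self.samples[0, 1] == 0.0 and self.samples[0, 2] == 0.0):
            raise ValueError("first sample must be at the origin")

    @property
    def t_ms(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    def distances_from_start(self) -> np.ndarray:
        return np.hypot(self.samples[:, 1], self.samples[:, 2])


def movement_angle(x_gu, y_gu):
    """Signed angle (degrees) of the start->sample chord relative to the
    start->target ray; counterclockwise positive, clockwise negative.

    The target lies straight up the +y axis, so a sample left of the
    target line (negative x) has a positive angle.  Vectorized.
    """
    x = np.asarray(x_gu, dtype=float)
    y = np.asarray(y_gu, dtype=float)
    if np.any((x == 0.0) & (y == 0.0)):
        raise InvalidTrialError("movement angle undefined at the origin")
    return np.degrees(np.arctan2(-x, y))


def _ia_index(traj: Trajectory, threshold_gu: float, distance_mode: str) -> int:
    if distance_mode == "euclidean":
        d = traj.distances_from_start()
    elif distance_mode == "arclength":
        steps = np.hypot(*np.diff(traj.xy, axis=0).T)
        d = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        raise ValueError("distance_mode must be 'euclidean' or 'arclength'")
    idx = np.nonzero(d >= threshold_gu)[0]
    if idx.size == 0:
        raise InvalidTrialError(
            f"no sample reaches the {threshold_gu} GU initial-angle threshold"
        )
    return int(idx[0])


def _onset_index(traj: Trajectory) -> int:
    """First sample with nonzero displacement after the click."""
    moved = np.any(np.diff(traj.xy, axis=0) != 0.0, axis=1)
    cand = np.nonzero(moved)[0] + 1
    if traj.t_click_ms is not None:
        cand = cand[traj.t_ms[cand] > traj.t_click_ms]
    if cand.size == 0:
        raise InvalidTrialError("no movement after the click")
    return int(cand[0])


def initial_angle(
    traj: Trajectory,
    threshold_gu: float = IA_THRESHOLD_GU,
    distance_mode: str = "euclidean",
) -> tuple[float, float]:
    """(IA in degrees, IA time in ms after movement onset).

    The IA sample is the first whose Euclidean distance from the start is
    >= ``threshold_gu`` (set ``distance_mode='arclength'`` for the
    along-path reading).
    """
    i = _ia_index(traj, threshold_gu, distance_mode)
    angle = float(movement_angle(traj.samples[i, 1], traj.samples[i, 2]))
    try:
        onset = _onset_index(traj)
        ia_time = float(traj.t_ms[i] - traj.t_ms[onset])
    except InvalidTrialError:
        ia_time = math.nan
    return angle, ia_time


def final_angle(traj: Trajectory) -> float:
    """Movement angle of the last sample (start-to-end chord)."""
    x, y = traj.samples[-1, 1], traj.samples[-1, 2]
    if x == 0.0 and y == 0.0:
        raise InvalidTrialError("trajectory ends at the origin; final angle undefined")
    return float(movement_angle(x, y))


def compensation_angle(final_deg: float, initial_deg: float) -> float:
    """Within-trial feedback correction: final minus initial angle."""
    return final_deg - initial_deg


def launch_angle(traj: Trajectory) -> float:
    """Start-to-end chord angle; the same computation as the final angle."""
    return final_angle(traj)


def path_length_ratio(traj: Trajectory) -> float:
    """Traveled path length divided by start-to-end distance; >= 1."""
    steps = np.hypot(*np.diff(traj.xy, axis=0).T)
    chord = float(np.hypot(*(traj.xy[-1] - traj.xy[0])))
    if chord == 0.0:
        raise InvalidTrialError("zero start-to-end distance; path length ratio undefined")
    return float(np.sum(steps) / chord)


def correction_metrics(
    traj: Trajectory,
    window_deg: float = CORRECTION_WINDOW_DEG,
    threshold_gu: float = IA_THRESHOLD_GU,
    distance_mode: str = "euclidean",
) -> float | None:
    """Normalized correction time, or ``None`` if the path never leaves the
    correction window.

    The correction window is the initial angle +/- ``window_deg``; the
    correction point is the first sample strictly after the IA sample
    whose movement angle falls outside it.  The time from movement onset
    to the correction point is divided by the movement time, giving a
    fraction in (0, 1].
    """
    i = _ia_index(traj, threshold_gu, distance_mode)
    ia = float(movement_angle(traj.samples[i, 1], traj.samples[i, 2]))
    after = traj.samples[i + 1 :]
    if after.shape[0] == 0:
        return None
    angles = movement_angle(after[:, 1], after[:, 2])
    outside = np.nonzero(np.abs(angles - ia) > window_deg)[0]
    if outside.size == 0:
        return None
    t_corr = float(after[outside[0], 0])
    onset = _onset_index(traj)
    movement_ms = float(traj.t_ms[-1] - traj.t_ms[onset])
    if movement_ms <= 0:
        return None
    return float((t_corr - traj.t_ms[onset]) / movement_ms)


def angle_spread(
    traj: Trajectory,
    threshold_gu: float = IA_THRESHOLD_GU,
    distance_mode: str = "euclidean",
) -> float:
    """Max minus min movement angle from the IA sample to the last sample."""
    i = _ia_index(traj, threshold_gu, distance_mode)
    seg = traj.samples[i:]
    angles = movement_angle(seg[:, 1], seg[:, 2])
    return float(np.max(angles) - np.min(angles))


def timing_measures(traj: Trajectory) -> tuple[float, float, float]:
    """(reaction_ms, stationary_ms, movement_ms).

    Reaction time runs from trial start to the click, stationary time
    from the click to movement onset (the first sample with nonzero
    displacement), and movement time from onset to the last sample.
    """
    if traj.t_click_ms is None:
        raise InvalidTrialError("event times missing; timing measures unavailable")
    onset = _onset_index(traj)
    reaction = float(traj.t_click_ms - traj.t_trial_start_ms)
    stationary = float(traj.t_ms[onset] - traj.t_click_ms)
    movement = float(traj.t_ms[-1] - traj.t_ms[onset])
    return reaction, stationary, movement


@dataclass
class TrialMeasures:
    """All per-trial scalars, plus a validity flag.

    Invariants (when valid): ``compensation == final - initial`` to
    machine precision, ``angle_spread >= |compensation|``, and
    ``path_length_ratio >= 1``.
    """

    initial_angle_deg: float = math.nan
    final_angle_deg: float = math.nan
    compensation_angle_deg: float = math.nan
    launch_angle_deg: float = math.nan
    path_length_ratio: float = math.nan
    norm_correction_time: float = math.nan
    angle_spread_deg: float = math.nan
    reaction_ms: float = math.nan
    stationary_ms: float = math.nan
    movement_ms: float = math.nan
    ia_time_ms: float = math.nan
    hit: bool | None = None
    valid: bool = True
    invalid_reason: str | None = None


def compute_trial_measures(
    traj: Trajectory,
    spec: TrialSpec | None = None,
    schedule: Schedule | None = None,
    *,
    ia_threshold_gu: float = IA_THRESHOLD_GU,
    correction_window_deg: float = CORRECTION_WINDOW_DEG,
    distance_mode: str = "euclidean",
) -> TrialMeasures:
    """Compute every measure for one trajectory; spatial-measure failures
    flag the trial invalid, missing event times only blank the timings."""
    m = TrialMeasures()
    try:
        fa = final_angle(traj)
        ia, ia_time = initial_angle(traj, ia_threshold_gu, distance_mode)
    except InvalidTrialError as err:
        m.valid = False
        m.invalid_reason = str(err)
        return m
    m.initial_angle_deg = ia
    m.final_angle_deg = fa
    m.compensation_angle_deg = compensation_angle(fa, ia)
    m.launch_angle_deg = fa
    m.ia_time_ms = ia_time
    m.path_length_ratio = path_length_ratio(traj)
    nct = correction_metrics(traj, correction_window_deg, ia_threshold_gu, distance_mode)
    m.norm_correction_time = math.nan if nct is None else nct
    m.angle_spread_deg = angle_spread(traj, ia_threshold_gu, distance_mode)
    try:
        m.reaction_ms, m.stationary_ms, m.movement_ms = timing_measures(traj)
    except InvalidTrialError:
        pass  # trial retained for spatial measures
    if spec is not None and schedule is not None:
        m.hit = evaluate_trial(displayed_angle(fa, spec), schedule)
    return m


#: Fixed column order of the per-trial measures table (the `extract` CSV).
MEASURES_COLUMNS = [
    "participant_id",
    "age_mo",
    "sex",
    "device",
    "task",
    "trial_index",
    "block",
    "rotation_deg",
    "clamp",
    "valid",
    "invalid_reason",
    "hit",
    "initial_angle_deg",
    "final_angle_deg",
    "compensation_angle_deg",
    "launch_angle_deg",
    "path_length_ratio",
    "norm_correction_time",
    "angle_spread_deg",
    "reaction_ms",
    "stationary_ms",
    "movement_ms",
    "ia_time_ms",
]


def session_measures(session, schedule: Schedule | None = None, **kwargs) -> pd.DataFrame:
    """One row of measures per trial of a session (see ``MEASURES_COLUMNS``).

    ``session`` is any object with participant metadata attributes and a
    ``trials`` list of (spec, trajectory) records, as produced by the
    simulator or read from session JSONL.  Normalized correction time is
    a Push-ball construct (there is no on-line steering to correct in
    Launch ball) and is left blank for Launch ball sessions.
    """
    if schedule is None:
        schedule = Schedule(task=session.task, trials=[r.spec for r in session.trials])
    rows = []
    n_invalid = 0
    for rec in session.trials:
        m = compute_trial_measures(rec.trajectory, rec.spec, schedule, **kwargs)
        if not m.valid:
            n_invalid += 1
            log.info(
                "participant %s trial %d invalid: %s",
                session.participant_id,
                rec.spec.trial_index,
                m.invalid_reason,
            )
        if session.task == "launchball":
            m.norm_correction_time = math.nan
        rows.append(
            {
                "participant_id": session.participant_id,
                "age_mo": session.age_mo,
                "sex": session.sex,
                "device": session.device,
                "task": session.task,
                "trial_index": rec.spec.trial_index,
                "block": rec.spec.block,
                "rotation_deg": rec.spec.rotation_deg,
                "clamp": rec.spec.clamp,
                "valid": m.valid,
                "invalid_reason": m.invalid_reason,
                "hit": m.hit,
                "initial_angle_deg": m.initial_angle_deg,
                "final_angle_deg": m.final_angle_deg,
                "compensation_angle_deg": m.compensation_angle_deg,
                "launch_angle_deg": m.launch_angle_deg,
                "path_length_ratio": m.path_length_ratio,
                "norm_correction_time": m.norm_correction_time,
                "angle_spread_deg": m.angle_spread_deg,
                "reaction_ms": m.reaction_ms,
                "stationary_ms": m.stationary_ms,
                "movement_ms": m.movement_ms,
                "ia_time_ms": m.ia_time_ms,
            }
        )
    if n_invalid:
        log.info("participant %s: %d invalid trials", session.participant_id, n_invalid)
    return pd.DataFrame(rows, columns=MEASURES_COLUMNS)


def measures_table(sessions: Iterable, **kwargs) -> pd.DataFrame:
    """Concatenated per-trial measures for a list of sessions."""
    frames = [session_measures(s, **kwargs) for s in sessions]
    if not frames:
        return pd.DataFrame(columns=MEASURES_COLUMNS)
    return pd.concat(frames, ignore_index=True)
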