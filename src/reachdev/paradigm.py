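"""Experimental task paradigm for the Push ball / Launch ball games.

Both games ask the participant to move an on-screen ball from a start
location to a target 24 game units (GU) straight ahead.  A session is four
sequential blocks — baseline, learning, error clamp, washout.  During
learning a clockwise visuomotor rotation is ramped in at 0.5 degrees per
trial over 60 trials and then held at 30 degrees for a further 30 trials,
so the displayed ball direction is rotated relative to the hand.  During
the error-clamp block the displayed ball moves nearly straight to the
target regardless of the hand, with a small random rotation (uniform on
[-2, 2] degrees) added each trial to mimic natural variation; every clamp
trial therefore succeeds, removing the error signal and exposing retained
adaptation.  Baseline and washout give veridical feedback.

Sign convention: clockwise angles are negative, counterclockwise positive.
The 30-degree clockwise rotation is stored as ``rotation_deg = -30``; full
compensation is a hand angle of +30.  Angles are measured from the
start-to-target ray (0 degrees), and a trial is a hit when the displayed
ball's final angle is within +/-10 degrees of the target center
(boundary inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrialSpec",
    "Schedule",
    "build_schedule",
    "displayed_angle",
    "evaluate_trial",
    "hand_success_zone",
    "TASKS",
    "BLOCK_ORDER",
    "BLOCK_LENGTHS",
    "TARGET_DISTANCE_GU",
    "SUCCESS_HALFWIDTH_DEG",
]

TASKS = ("pushball", "launchball")
BLOCK_ORDER = ("baseline", "learning", "clamp", "washout")

#: Trials per block.  Session totals are 160 (Push ball) and 180 (Launch
#: ball); Launch ball gets extra baseline trials to learn the less
#: naturalistic interface, all other blocks are identical.
BLOCK_LENGTHS = {
    "pushball": {"baseline": 20, "learning": 90, "clamp": 20, "washout": 30},
    "launchball": {"baseline": 40, "learning": 90, "clamp": 20, "washout": 30},
}

TARGET_DISTANCE_GU = 24.0
SUCCESS_HALFWIDTH_DEG = 10.0
ROTATION_STEP_DEG = -0.5
N_RAMP_TRIALS = 60
N_HOLD_TRIALS = 30
CLAMP_JITTER_MAX_DEG = 2.0


@dataclass(frozen=True)
class TrialSpec:
    """The perturbation program of a single trial.

    ``rotation_deg`` is the signed rotation applied to the displayed ball
    (clockwise negative); it is 0 on baseline and washout trials.
    ``clamp_jitter_deg`` is the small random rotation shown on error-clamp
    trials and is ``None`` everywhere else.
    """

    trial_index: int
    block: str
    rotation_deg: float
    clamp: bool
    clamp_jitter_deg: float | None = None

    def __post_init__(self) -> None:
        if self.block not in BLOCK_ORDER:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCK_ORDER}")
        if self.clamp != (self.block == "clamp"):
            raise ValueError("clamp flag must be set exactly on clamp-block trials")
        if self.clamp:
            if self.clamp_jitter_deg is None:
                raise ValueError("clamp trials require clamp_jitter_deg")
            if abs(self.clamp_jitter_deg) > CLAMP_JITTER_MAX_DEG:
                raise ValueError("|clamp_jitter_deg| must be <= 2 degrees")
        elif self.clamp_jitter_deg is not None:
            raise ValueError("clamp_jitter_deg only present on clamp trials")
        if self.block in ("baseline", "washout") and self.rotation_deg != 0.0:
            raise ValueError(f"{self.block} trials are unperturbed (rotation_deg must be 0)")


@dataclass
class Schedule:
    """Ordered trial program of one session plus task geometry."""

    task: str
    trials: list[TrialSpec]
    target_distance_gu: float = TARGET_DISTANCE_GU
    success_halfwidth_deg: float = SUCCESS_HALFWIDTH_DEG

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_in_block(self, block: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.block == block]

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "target_distance_gu": self.target_distance_gu,
            "success_halfwidth_deg": self.success_halfwidth_deg,
            "trials": [
                {
                    "trial_index": t.trial_index,
                    "block": t.block,
                    "rotation_deg": t.rotation_deg,
                    "clamp": t.clamp,
                    "clamp_jitter_deg": t.clamp_jitter_deg,
                }
                for t in self.trials
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        payload = json.loads(text)
        trials = [
            TrialSpec(
                trial_index=d["trial_index"],
                block=d["block"],
                rotation_deg=d["rotation_deg"],
                clamp=d["clamp"],
                clamp_jitter_deg=d.get("clamp_jitter_deg"),
            )
            for d in payload["trials"]
        ]
        return cls(
            task=payload["task"],
            trials=trials,
            target_distance_gu=payload["target_distance_gu"],
            success_halfwidth_deg=payload["success_halfwidth_deg"],
        )


def learning_rotation_deg(k: int) -> float:
    """Rotation on the k-th learning trial (1-based): 0.5 deg/trial ramp to
    -30 over 60 trials, then held at -30 for 30 trials."""
    if not 1 <= k <= N_RAMP_TRIALS + N_HOLD_TRIALS:
        raise ValueError(f"learning trial index {k} out of range")
    if k <= N_RAMP_TRIALS:
        return ROTATION_STEP_DEG * k
    return ROTATION_STEP_DEG * N_RAMP_TRIALS


def build_schedule(task: str, seed: int) -> Schedule:
    """Build the full trial schedule for one session.

    Clamp-trial jitters are drawn uniformly on [-2, 2] degrees from a
    generator seeded with ``seed`` (one draw per clamp trial), so the
    schedule is reproducible.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks are {', '.join(TASKS)}")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = BLOCK_LENGTHS[task]
    jitters = np.round(
        rng.uniform(-CLAMP_JITTER_MAX_DEG, CLAMP_JITTER_MAX_DEG, size=lengths["clamp"]), 6
    )

    trials: list[TrialSpec] = []
    idx = 0
    for block in BLOCK_ORDER:
        for k in range(1, lengths[block] + 1):
            idx += 1
            if block == "learning":
                rot = learning_rotation_deg(k)
            else:
                rot = 0.0
            trials.append(
                TrialSpec(
                    trial_index=idx,
                    block=block,
                    rotation_deg=rot,
                    clamp=block == "clamp",
                    clamp_jitter_deg=float(jitters[k - 1]) if block == "clamp" else None,
                )
            )
    return Schedule(task=task, trials=trials)


def displayed_angle(hand_angle_deg: float, spec: TrialSpec) -> float:
    """Angle of the displayed ball given the hand angle.

    Non-clamp trials show the hand angle plus the trial's rotation; clamp
    trials show only the small jitter, regardless of the hand.
    """
    if spec.clamp:
        return float(spec.clamp_jitter_deg)
    return float(hand_angle_deg + spec.rotation_deg)


def evaluate_trial(displayed_final_deg: float, schedule: Schedule) -> bool:
    """Hit iff the displayed final angle is within the success window
    (boundary inclusive)."""
    return abs(displayed_final_deg) <= schedule.success_halfwidth_deg


def hand_success_zone(spec: TrialSpec, schedule: Schedule) -> tuple[float, float]:
    """Interval of hand-space angles that register a hit on this trial.

    The window is ``[-rotation - halfwidth, -rotation + halfwidth]``; e.g.
    under the held -30 degree rotation a hand angle between 20 and 40
    degrees succeeds.  Undefined for clamp trials, which succeed by
    construction.
    """
    if spec.clamp:
        raise ValueError("clamp trials have no hand-space success zone (always a hit)")
    h = schedule.success_halfwidth_deg
    return (-spec.rotation_deg - h, -spec.rotation_deg + h)
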