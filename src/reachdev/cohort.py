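"""Synthetic participants for the visuomotor-rotation games.

Each participant is a single-rate state-space learner: the planned reach
direction (the internal state x, in degrees) evolves trial to trial as

    x[n+1] = A * x[n] - B * e[n]

where A is retention, B the learning rate, and e[n] the displayed error —
the on-screen ball angle at the point where the initial angle is read out
(on error-clamp trials, e is the clamp jitter, so the state decays
geometrically at rate A).  Within a trial, Push ball participants can
additionally steer: after a visual-delay fraction of the movement the
heading relaxes toward the hand angle that would zero the displayed
error, and the feedback gain G in [0, 1] sets the fraction of the
remaining error corrected by movement end.  Launch ball and clamp trials
give no usable on-line feedback, so G is treated as 0 there.

Ages parameterize the cohort: the generator's end-of-learning adaptation
target follows an inverse-age law a + b/age_mo (rising toward a in
adulthood), the overall-performance target follows its own inverse-age
law, and the gap between them — filled by feedback steering — shrinks
with age.  Planning/motor noise and reaction, stationary, and movement
times all decrease with age.  Trajectories are sampled at the
participant's polling rate with multiplicative timing jitter;
stationary periods produce no samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io import Session, TrialRecord
from .kinematics import Trajectory, initial_angle
from .paradigm import (
    N_HOLD_TRIALS,
    N_RAMP_TRIALS,
    ROTATION_STEP_DEG,
    Schedule,
    TrialSpec,
    build_schedule,
    learning_rotation_deg,
)

__all__ = [
    "ParticipantParams",
    "CohortConfig",
    "ADULT_AGE_MO",
    "end_learning_target",
    "end_learning_adaptation",
    "solve_learning_rate",
    "default_age_params",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
]

MIN_AGE_MO = 36
ADULT_AGE_MO = 216
RETENTION_DEFAULT = 0.98
#: Fraction of the movement extent covered before visual feedback can
#: steer the heading (≈150–180 ms visual delay relative to child
#: movement times).
VISUAL_DELAY_FRAC = 0.25
_MAX_AIM_DEG = 75.0
_TARGET_CAP_DEG = 28.0  # targets above this are unreachable for A=0.98 learners


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one synthetic participant."""

    participant_id: str
    age_mo: float
    retention_A: float
    learning_rate_B: float
    feedback_gain_G: float
    plan_sd_deg: float
    motor_sd_deg: float
    rt_mean_ms: float
    st_mean_ms: float
    mt_mean_ms: float
    polling_hz: float
    device: str = "mouse"
    sex: str = "F"

    def __post_init__(self) -> None:
        for name in ("retention_A", "learning_rate_B", "feedback_gain_G"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("plan_sd_deg", "motor_sd_deg", "rt_mean_ms", "st_mean_ms", "mt_mean_ms", "polling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    ``inverse_curve_a_deg``/``_b_deg_mo`` set the cohort's end-of-learning
    adaptation law a + b/age_mo; ``fa_curve_*`` the same for overall
    performance (final angle).  Defaults are the developmental shape the
    pipeline is meant to recover.
    """

    n_participants: int = 200
    age_range_mo: tuple[float, float] = (36.0, 216.0)
    inverse_curve_a_deg: float = 25.16
    inverse_curve_b_deg_mo: float = -720.9
    fa_curve_a_deg: float = 29.7
    fa_curve_b_deg_mo: float = -295.3
    ia_target_sd_deg: float = 5.0
    fa_target_sd_deg: float = 2.5
    ages_mo: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.age_range_mo
        if not (MIN_AGE_MO <= lo <= hi <= 600):
            raise ValueError("age_range_mo must lie within [36, 600]")


def end_learning_target(age_mo: float, cohort: CohortConfig) -> float:
    """The cohort's deterministic adaptation target at ``age_mo``:
    clip(a + b/age_mo, 0, 30)."""
    return float(
        np.clip(cohort.inverse_curve_a_deg + cohort.inverse_curve_b_deg_mo / age_mo, 0.0, 30.0)
    )


def _learning_rotations() -> np.ndarray:
    return np.array(
        [learning_rotation_deg(k) for k in range(1, N_RAMP_TRIALS + N_HOLD_TRIALS + 1)]
    )


def end_learning_adaptation(retention_A: float, learning_rate_B: float) -> float:
    """Mean state over the last 10 learning trials of the deterministic
    (noise-free, G=0) single-rate learner driven by the standard ramp."""
    rots = _learning_rotations()
    x = 0.0
    xs = np.empty(rots.size)
    for n, r in enumerate(rots):
        xs[n] = x
        e = x + r
        x = retention_A * x - learning_rate_B * e
    return float(xs[-10:].mean())


def solve_learning_rate(target_deg: float, retention_A: float = RETENTION_DEFAULT) -> float:
    """Learning rate B for which the deterministic learner's end-of-learning
    adaptation equals ``target_deg``."""
    if target_deg <= 1e-9:
        return 0.0
    target = min(target_deg, _TARGET_CAP_DEG)
    f = lambda b: end_learning_adaptation(retention_A, b) - target
    return float(brentq(f, 0.0, 0.9999, xtol=1e-10))


def _age_decay(age_mo: float, floor: float, span: float, tau_mo: float) -> float:
    return floor + span * float(np.exp(-(age_mo - MIN_AGE_MO) / tau_mo))


def default_age_params(age_mo: float, cohort: CohortConfig, seed: int) -> ParticipantParams:
    """Draw one participant's generative parameters at a given age.

    Retention is fixed at 0.98; the learning rate is solved so that the
    deterministic learner hits the cohort's (jittered) end-of-learning
    adaptation target; the feedback gain is set so the expected final
    angle approaches the overall-performance target.  Noise and timing
    parameters decay exponentially with age.  All jitter comes from a
    generator seeded with ``seed``, so the draw is reproducible.
    """
    if age_mo < MIN_AGE_MO:
        raise ValueError(f"age_mo must be >= {MIN_AGE_MO} months (study range)")
    rng = np.random.default_rng(seed)
    ia_target = float(
        np.clip(
            end_learning_target(age_mo, cohort) + rng.normal(0.0, cohort.ia_target_sd_deg),
            0.0,
            _TARGET_CAP_DEG,
        )
    )
    fa_raw = cohort.fa_curve_a_deg + cohort.fa_curve_b_deg_mo / age_mo
    fa_target = float(
        np.clip(fa_raw + rng.normal(0.0, cohort.fa_target_sd_deg), ia_target, 29.5)
    )
    B = solve_learning_rate(ia_target)
    G = float(np.clip((fa_target - ia_target) / max(30.0 - ia_target, 1e-6), 0.0, 1.0))
    jit = lambda sd: float(rng.lognormal(0.0, sd))
    return ParticipantParams(
        participant_id=f"age{age_mo:.0f}mo-{seed}",
        age_mo=float(age_mo),
        retention_A=RETENTION_DEFAULT,
        learning_rate_B=B,
        feedback_gain_G=G,
        plan_sd_deg=_age_decay(age_mo, 3.0, 9.0, 90.0) * jit(0.15),
        motor_sd_deg=_age_decay(age_mo, 1.0, 2.0, 90.0) * jit(0.15),
        rt_mean_ms=_age_decay(age_mo, 500.0, 1500.0, 80.0) * jit(0.15),
        st_mean_ms=_age_decay(age_mo, 120.0, 500.0, 80.0) * jit(0.2),
        mt_mean_ms=_age_decay(age_mo, 800.0, 1700.0, 80.0) * jit(0.15),
        polling_hz=float(rng.uniform(40.0, 90.0)),
        device=str(rng.choice(["mouse", "trackpad", "touchscreen"], p=[0.6, 0.25, 0.15])),
        sex=str(rng.choice(["F", "M"])),
    )


def simulate_trial(
    state_deg: float,
    spec: TrialSpec,
    params: ParticipantParams,
    task: str,
    rng: np.random.Generator,
    *,
    visual_delay_frac: float = VISUAL_DELAY_FRAC,
    target_distance_gu: float = 24.0,
) -> tuple[Trajectory, float]:
    """Simulate one trial; returns the hand trajectory and the next state.

    The plan is the state plus planning noise.  Push ball non-clamp
    trials steer: after ``visual_delay_frac`` of the movement extent the
    heading relaxes exponentially toward the hand angle that zeroes the
    displayed error, closing fraction G of the gap by movement end.
    Clamp and Launch ball trials do not steer.  Samples are emitted at
    the participant's polling rate with 20% multiplicative timing jitter;
    a Push ball trial ends when the displayed ball crosses the target
    plane (y = 24 GU).  The state update uses the displayed angle at the
    initial-angle threshold point (clamp trials: the clamp jitter).
    """
    if not np.isfinite(state_deg):
        raise ValueError("state must be finite")
    plan = float(np.clip(state_deg + rng.normal(0.0, params.plan_sd_deg), -_MAX_AIM_DEG, _MAX_AIM_DEG))
    steering = task == "pushball" and not spec.clamp and params.feedback_gain_G > 0.0
    if steering:
        hand_target = -spec.rotation_deg
        final_aim = float(
            np.clip(plan + params.feedback_gain_G * (hand_target - plan), -_MAX_AIM_DEG, _MAX_AIM_DEG)
        )
    else:
        final_aim = plan

    t_click = float(rng.lognormal(np.log(params.rt_mean_ms), 0.2))
    t_onset = t_click + float(rng.lognormal(np.log(params.st_mean_ms), 0.25))
    mt = float(rng.lognormal(np.log(params.mt_mean_ms), 0.15))

    rot = 0.0 if spec.clamp else spec.rotation_deg
    # radial speed sized so the displayed ball reaches the target plane in ~mt
    end_cos = max(float(np.cos(np.radians(final_aim + rot))), 0.25)
    speed = target_distance_gu / end_cos / mt  # GU per ms
    dt_nom = 1000.0 / params.polling_hz
    delay_s = visual_delay_frac * target_distance_gu
    kappa = 5.0 / max(target_distance_gu - delay_s, 1e-6)

    n_max = 20000
    dts = dt_nom * rng.uniform(0.8, 1.2, size=256)
    noises = rng.normal(0.0, params.motor_sd_deg, size=256)
    rows = [(t_click, 0.0, 0.0)]
    t, s = t_onset - dts[0], 0.0  # first movement sample lands at ~t_onset
    i = 0
    while i < n_max:
        if i >= dts.size:
            dts = np.concatenate([dts, dt_nom * rng.uniform(0.8, 1.2, size=256)])
            noises = np.concatenate([noises, rng.normal(0.0, params.motor_sd_deg, size=256)])
        t += dts[i]
        s += speed * dts[i]
        if steering and s > delay_s:
            theta = final_aim + (plan - final_aim) * float(np.exp(-kappa * (s - delay_s)))
        else:
            theta = plan
        # motor noise is positional: its angular footprint is full at the
        # IA readout distance (1.2 GU) and decays ~1/s beyond it, so the
        # initial angle carries sd ~= motor_sd while late samples wiggle
        # by a roughly constant lateral offset
        theta_n = theta + noises[i] * (1.2 / max(s, 1.2))
        rad = np.radians(theta_n)
        x = -s * float(np.sin(rad))
        y = s * float(np.cos(rad))
        rows.append((t, x, y))
        if spec.clamp:
            y_disp = y  # clamped ball tracks the hand's y speed
        else:
            y_disp = s * float(np.cos(np.radians(theta_n + rot)))
        if y_disp >= target_distance_gu:
            break
        i += 1

    traj = Trajectory(samples=np.array(rows), t_trial_start_ms=0.0, t_click_ms=t_click)
    if spec.clamp:
        err = float(spec.clamp_jitter_deg)
    else:
        ia, _ = initial_angle(traj)
        err = ia + spec.rotation_deg
    next_state = params.retention_A * state_deg - params.learning_rate_B * err
    return traj, float(next_state)


def simulate_session(
    params: ParticipantParams,
    schedule: Schedule,
    rng: np.random.Generator,
    *,
    sex: str | None = None,
    device: str | None = None,
) -> Session:
    """Run a full session from a zero initial state."""
    session = Session(
        participant_id=params.participant_id,
        age_mo=params.age_mo,
        sex=sex if sex is not None else params.sex,
        device=device if device is not None else params.device,
        task=schedule.task,
    )
    state = 0.0
    for spec in schedule.trials:
        traj, state = simulate_trial(state, spec, params, schedule.task, rng)
        session.trials.append(TrialRecord(spec=spec, trajectory=traj))
    return session


def simulate_cohort(cohort: CohortConfig, task: str) -> list[Session]:
    """Simulate one full session per participant.

    Each participant gets an independent generator derived from
    (cohort.seed, participant index), so cohorts are reproducible and
    participants are order-independent.
    """
    sessions = []
    lo, hi = cohort.age_range_mo
    for i in range(cohort.n_participants):
        rng = np.random.default_rng([cohort.seed, i])
        if cohort.ages_mo is not None:
            age = float(cohort.ages_mo[i % len(cohort.ages_mo)])
        else:
            age = float(rng.uniform(lo, hi))
        param_seed = int(rng.integers(2**31))
        try:
            params = replace(
                default_age_params(age, cohort, param_seed),
                participant_id=f"P{i:04d}",
            )
            sched_seed = int(rng.integers(2**31))
            schedule = build_schedule(task, sched_seed)
            sessions.append(simulate_session(params, schedule, rng))
        except ValueError as err:
            raise ValueError(f"participant {i} (age {age:.1f} mo): {err}") from err
    return sessions
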