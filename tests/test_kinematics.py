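import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bruteforce as bf
from reachdev.kinematics import (
    InvalidTrialError,
    Trajectory,
    angle_spread,
    compensation_angle,
    compute_trial_measures,
    correction_metrics,
    final_angle,
    initial_angle,
    launch_angle,
    movement_angle,
    path_length_ratio,
    timing_measures,
)


def traj_from(points, t_click=None, t0=0.0):
    """Trajectory from (x, y) points at uniform 10 ms spacing."""
    points = np.asarray(points, dtype=float)
    start = 100.0 if t_click is None else t_click
    t = start + 10.0 * np.arange(len(points))
    return Trajectory(
        samples=np.column_stack([t, points]), t_trial_start_ms=t0, t_click_ms=t_click
    )


def straight_path(angle_deg, n=20, length=24.0):
    s = np.linspace(0.0, length, n)
    rad = math.radians(angle_deg)
    return np.column_stack([-s * math.sin(rad), s * math.cos(rad)])


class TestMovementAngle:
    @pytest.mark.parametrize(
        "x,y,expected", [(0, 10, 0.0), (-10, 10, 45.0), (10, 10, -45.0), (-6, 24, 14.0362)]
    )
    def test_examples(self, x, y, expected):
        assert movement_angle(x, y) == pytest.approx(expected, abs=1e-3)

    def test_origin_rejected(self):
        with pytest.raises(InvalidTrialError):
            movement_angle(0.0, 0.0)


class TestInitialAngle:
    def test_straight_path(self):
        ia, _ = initial_angle(traj_from(straight_path(30.0)))
        assert ia == pytest.approx(30.0, abs=1e-9)

    def test_threshold_crossed_before_turn(self):
        # heading 0 for the first 2 GU, then a 40-degree turn
        first = straight_path(0.0, n=5, length=2.0)
        rad = math.radians(40.0)
        turn = first[-1] + np.cumsum(
            np.tile([-0.5 * math.sin(rad), 0.5 * math.cos(rad)], (10, 1)), axis=0
        )
        ia, _ = initial_angle(traj_from(np.vstack([first, turn])))
        assert ia == pytest.approx(0.0, abs=1e-9)

    def test_unreached_threshold_flags_invalid(self):
        tiny = traj_from([[0, 0], [0.1, 0.2], [0.2, 0.4]])
        with pytest.raises(InvalidTrialError):
            initial_angle(tiny)
        m = compute_trial_measures(tiny)
        assert not m.valid and "threshold" in m.invalid_reason


def test_final_and_launch_angle_are_the_endpoint_chord():
    pts = np.array([[0, 0], [3, 5], [-8, 12], [-6, 24.0]])
    traj = traj_from(pts)
    expected = math.degrees(math.atan2(6, 24))
    assert final_angle(traj) == pytest.approx(expected, abs=1e-9)
    assert launch_angle(traj) == pytest.approx(final_angle(traj))
    on_line = traj_from([[0, 0], [4, 10], [0, 24.0]])
    assert final_angle(on_line) == pytest.approx(0.0)


def test_compensation_is_final_minus_initial():
    assert compensation_angle(30.0, 12.0) == pytest.approx(18.0)
    assert compensation_angle(25.0, 25.0) == 0.0
    assert compensation_angle(-5.0, 10.0) == pytest.approx(-15.0)


class TestPathLengthRatio:
    def test_straight_is_one(self):
        assert path_length_ratio(traj_from(straight_path(12.0))) == pytest.approx(1.0)

    def test_perpendicular_segments(self):
        traj = traj_from([[0, 0], [0, 10], [10, 10.0]])
        assert path_length_ratio(traj) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_zero_chord_flags_invalid(self):
        loop = traj_from([[0, 0], [5, 5], [0, 0.0]])
        with pytest.raises(InvalidTrialError):
            path_length_ratio(loop)


class TestCorrectionMetrics:
    def test_constant_heading_never_corrects(self):
        assert correction_metrics(traj_from(straight_path(20.0), t_click=90.0)) is None

    def test_hand_checked_fixture(self):
        # 0-degree heading for 6 samples (IA read at sample 2, 1.5 GU),
        # then an abrupt 20-degree dogleg: first sample outside IA +/- 5
        # is the first turned sample
        ahead = straight_path(0.0, n=6, length=7.5)
        rad = math.radians(20.0)
        turn = ahead[-1] + np.cumsum(
            np.tile([-2 * math.sin(rad), 2 * math.cos(rad)], (6, 1)), axis=0
        )
        traj = traj_from(np.vstack([ahead, turn]), t_click=95.0)
        got = correction_metrics(traj)
        angles = [bf.angle_of(x, y) for _, x, y in traj.samples[1:]]
        first_out = next(j for j, a in enumerate(angles[1:], start=2) if abs(a - angles[0]) > 5)
        onset = 1  # first moving sample
        expected = (traj.t_ms[first_out] - traj.t_ms[onset]) / (traj.t_ms[-1] - traj.t_ms[onset])
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0 < got <= 1


class TestAngleSpread:
    def test_straight_is_zero(self):
        assert angle_spread(traj_from(straight_path(25.0))) == pytest.approx(0.0, abs=1e-9)

    def test_known_span(self):
        # samples past the IA point at angles 10..35 degrees
        angles = [10, 22, 35, 28, 15]
        pts = [[0, 0]] + [
            [-5 * math.sin(math.radians(a)), 5 * math.cos(math.radians(a))] for a in angles
        ]
        assert angle_spread(traj_from(pts)) == pytest.approx(25.0, abs=1e-9)


class TestTimingMeasures:
    def test_event_arithmetic(self):
        samples = np.array([[800.0, 0, 0], [950.0, 0.5, 1.0], [2150.0, 0, 24]])
        traj = Trajectory(samples=samples, t_trial_start_ms=0.0, t_click_ms=800.0)
        assert timing_measures(traj) == pytest.approx((800.0, 150.0, 1200.0))

    def test_immediate_movement_has_zero_stationary(self):
        samples = np.array([[500.0, 0, 0], [500.0 + 1e-9, 0.4, 0.8], [900.0, 0, 24]])
        traj = Trajectory(samples=samples, t_trial_start_ms=0.0, t_click_ms=500.0)
        _, stationary, _ = timing_measures(traj)
        assert stationary == pytest.approx(0.0, abs=1e-6)

    def test_missing_click_blanks_timings_only(self):
        traj = traj_from(straight_path(10.0))
        m = compute_trial_measures(traj)
        assert m.valid and math.isnan(m.reaction_ms)
        assert m.initial_angle_deg == pytest.approx(10.0)


def test_measures_match_bruteforce_on_random_fixtures(trajectory_factory):
    rng = np.random.default_rng(42)
    checked_corrections = 0
    for _ in range(500):
        traj = trajectory_factory(rng)
        samples = [tuple(row) for row in traj.samples]
        i, ia_oracle = bf.ia_scan(samples)
        ia, _ = initial_angle(traj)
        assert ia == pytest.approx(ia_oracle, abs=1e-9)
        assert final_angle(traj) == pytest.approx(bf.final_angle_scan(samples), abs=1e-9)
        assert path_length_ratio(traj) == pytest.approx(
            bf.path_length_ratio_scan(samples), abs=1e-9
        )
        spread = angle_spread(traj)
        assert spread == pytest.approx(bf.angle_spread_scan(samples), abs=1e-9)
        nct = correction_metrics(traj)
        nct_oracle = bf.correction_scan(samples, traj.t_click_ms)
        if nct_oracle is None:
            assert nct is None
        else:
            checked_corrections += 1
            assert nct == pytest.approx(nct_oracle, abs=1e-9)
        assert timing_measures(traj) == pytest.approx(
            bf.timing_scan(samples, traj.t_trial_start_ms, traj.t_click_ms), abs=1e-9
        )
        m = compute_trial_measures(traj)
        assert m.compensation_angle_deg == m.final_angle_deg - m.initial_angle_deg
        assert m.angle_spread_deg >= abs(m.compensation_angle_deg) - 1e-9
        assert m.path_length_ratio >= 1.0 - 1e-12
    assert checked_corrections > 100  # the fixtures genuinely exercise the scan


@pytest.mark.parametrize("theta", [-30.0, -15.0, 15.0, 30.0])
def test_rotation_equivariance(theta, trajectory_factory):
    rng = np.random.default_rng(7)
    rad = math.radians(theta)
    rot = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
    checked = 0
    while checked < 20:
        traj = trajectory_factory(rng)
        # the shift-by-theta identity only holds away from the +/-180
        # branch cut of the chord angle; real reaches never approach it
        angles = movement_angle(traj.xy[1:, 0], traj.xy[1:, 1])
        if np.max(np.abs(angles)) > 145.0:
            continue
        checked += 1
        rotated = Trajectory(
            samples=np.column_stack([traj.t_ms, traj.xy @ rot.T]),
            t_trial_start_ms=traj.t_trial_start_ms,
            t_click_ms=traj.t_click_ms,
        )
        ia0, _ = initial_angle(traj)
        ia1, _ = initial_angle(rotated)
        assert ia1 == pytest.approx(ia0 + theta, abs=1e-9)
        assert final_angle(rotated) == pytest.approx(final_angle(traj) + theta, abs=1e-9)
        assert launch_angle(rotated) == pytest.approx(launch_angle(traj) + theta, abs=1e-9)
        assert path_length_ratio(rotated) == pytest.approx(path_length_ratio(traj), abs=1e-9)
        assert angle_spread(rotated) == pytest.approx(angle_spread(traj), abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    angle=st.floats(-170.0, 170.0),
    r=st.floats(0.1, 50.0),
)
def test_movement_angle_polar_round_trip(angle, r):
    """The chord angle of a point placed at polar angle theta (CCW from
    the target ray) is theta itself, for any radius."""
    rad = math.radians(angle)
    got = movement_angle(-r * math.sin(rad), r * math.cos(rad))
    assert got == pytest.approx(angle, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.1, 5)), min_size=2, max_size=30))
def test_path_length_ratio_at_least_one(steps):
    """Any polyline is at least as long as its chord."""
    xy = np.vstack([[0.0, 0.0], np.cumsum(np.asarray(steps), axis=0)])
    if math.hypot(*(xy[-1] - xy[0])) < 1e-9:
        return
    t = 100.0 + 10.0 * np.arange(len(xy))
    traj = Trajectory(samples=np.column_stack([t, xy]))
    assert path_length_ratio(traj) >= 1.0 - 1e-12


def test_trajectory_invariants_enforced():
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(samples=np.array([[0.0, 0, 0], [0.0, 1, 1]]))
    with pytest.raises(ValueError, match="origin"):
        Trajectory(samples=np.array([[0.0, 1, 0], [10.0, 1, 1]]))
    with pytest.raises(ValueError, match="2 samples"):
        Trajectory(samples=np.array([[0.0, 0, 0]]))
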