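import numpy as np
import pytest

from reachdev.cohort import CohortConfig, simulate_cohort
from reachdev.epochs import extract_epochs
from reachdev.kinematics import Trajectory, measures_table


def make_random_trajectory(rng, n_min=5, n_max=40):
    """Random piecewise-linear trajectory with forward drift; always
    reaches the 1.2 GU initial-angle threshold."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        dts = rng.uniform(5.0, 40.0, size=n - 1)
        t_click = float(rng.uniform(200.0, 1500.0))
        t = t_click + np.concatenate([[0.0], np.cumsum(dts)])
        steps = rng.normal([0.0, 1.0], [1.2, 1.2], size=(n - 1, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        d = np.hypot(xy[:, 0], xy[:, 1])
        if d.max() >= 1.5 and d[-1] > 1e-6:
            break
    samples = np.column_stack([t, xy])
    return Trajectory(samples=samples, t_trial_start_ms=0.0, t_click_ms=t_click)


@pytest.fixture(scope="session")
def trajectory_factory():
    return make_random_trajectory


@pytest.fixture(scope="session")
def pushball_cohort():
    """A moderate default-parameter cohort shared across tests: sessions,
    per-trial measures, and epoch summaries."""
    cfg = CohortConfig(n_participants=80, seed=202)
    sessions = simulate_cohort(cfg, "pushball")
    measures = measures_table(sessions)
    epochs = extract_epochs(measures)
    return sessions, measures, epochs
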