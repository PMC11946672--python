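import numpy as np
import pytest
from hypothesis import settings

from gazerig.config import RunConfig
from gazerig.geometry import ScreenGeometry
from gazerig.pipeline import run_brightness_experiment, run_pattern_trials
from gazerig.rig import plan_calibration_grid

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def grid_fixations_100():
    """Fixation windows from 100 simulated calibration-grid trials at the
    default noise and motor settings (shared across metric tests)."""
    cfg = RunConfig(seed=11, n_trials=100)
    return run_pattern_trials(cfg, plan_calibration_grid()), cfg


@pytest.fixture(scope="session")
def brightness_run():
    """One full scaled brightness experiment (20 participants x 50
    saccades x 3 conditions)."""
    return run_brightness_experiment(RunConfig(seed=5))


def brute_force_runs(above, min_run):
    """Exhaustive scan for maximal runs of True of length >= min_run;
    the independent oracle for the detector's run logic."""
    runs, start = [], None
    for i, flag in enumerate(list(above) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
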