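import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitfpc as g

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return g.GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def default_trial(default_config):
    return g.simulate_trial(default_config)


@pytest.fixture(scope="session")
def pipe_config():
    return g.PipelineConfig()


@pytest.fixture(scope="session")
def analyzed(default_trial, pipe_config):
    return g.analyze_trial(default_trial, pipe_config)


def match_within(detected: np.ndarray, truth: np.ndarray, tol: int = 1):
    """Fraction of truth events with a detected event within tol samples."""
    if truth.size == 0:
        return 1.0
    if detected.size == 0:
        return 0.0
    d = np.abs(detected[:, None] - truth[None, :])
    return float(np.mean(d.min(axis=0) <= tol))


def event_match_stats(table, truth_table, tol: int = 1):
    """(fraction of truth events matched within tol, false-positive count)."""
    matched, total, false_pos = 0, 0, 0
    for kind in ("heel_strikes", "toe_offs"):
        for side in ("left", "right"):
            det = getattr(table, kind)[side]
            tru = getattr(truth_table, kind)[side]
            total += tru.size
            if tru.size and det.size:
                d = np.abs(det[:, None] - tru[None, :])
                matched += int(np.sum(d.min(axis=0) <= tol))
                false_pos += int(np.sum(d.min(axis=1) > tol))
            else:
                false_pos += det.size
    return matched / total, false_pos
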