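import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def short_session():
    """A 2-minute session config used where full-hour sessions are overkill."""
    from strobe import SessionConfig

    return SessionConfig(duration=120.0, seed=11)


def trapezoid(amplitude: int, rise: int, hold: int, fall: int) -> np.ndarray:
    """Sampled trapezoidal pulse used as a hand-walkable detector fixture."""
    return np.concatenate(
        [
            amplitude * np.arange(1, rise + 1) / rise,
            np.full(hold, float(amplitude)),
            amplitude * (1.0 - np.arange(1, fall + 1) / fall),
        ]
    )


def naive_running_min(values: np.ndarray, window: int) -> np.ndarray:
    """Brute-force trailing-window minimum: each window recomputed in full.

    Independent oracle for the streaming/block implementations.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    v = np.asarray(values)
    if v.size == 0:
        return v.copy()
    window = min(window, v.size) if v.size < window else window
    head = np.minimum.accumulate(v[: window - 1]) if window > 1 else np.empty(0, v.dtype)
    if v.size < window:
        return np.minimum.accumulate(v)
    body = sliding_window_view(v, window).min(axis=1)
    return np.concatenate([head, body])
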