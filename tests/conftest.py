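import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tv_distance(p, q):
    """Total-variation distance between two pmfs on a common support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = max(p.size, q.size)
    p = np.pad(p, (0, n - p.size))
    q = np.pad(q, (0, n - q.size))
    return 0.5 * np.abs(p - q).sum()


@pytest.fixture(scope="session")
def square_params():
    """Noise-free square-wave input: k_b pulsing 0.8/0.1, ON=OFF=100 s."""
    from pulsedecode.signal_gen import SignalParams

    return SignalParams(
        upper_mean=0.8,
        lower_mean=0.1,
        on_time_mean=100.0,
        off_time_mean=100.0,
        total_time=410.0,
    )


@pytest.fixture(scope="session")
def square_signal(square_params):
    from pulsedecode.signal_gen import make_am_signal

    return make_am_signal(square_params, rng=0)
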