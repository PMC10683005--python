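import numpy as np
import pytest

from cadlink.models import Trace
from cadlink.pipeline import run_pipeline
from cadlink.synthetic import FixtureSpec, generate


def gaussian_trace(apex=10.0, sigma=0.05, height=1.0, rate=2.0,
                   span=3.0, detector="CAD", baseline=0.0):
    """Uniformly sampled Gaussian peak trace (times in minutes)."""
    dt = 1.0 / (60.0 * rate)
    t = np.arange(apex - span, apex + span + dt / 2, dt)
    y = height * np.exp(-0.5 * ((t - apex) / sigma) ** 2) + baseline
    return Trace(detector, t, y, sampling_rate_hint=rate)


@pytest.fixture(scope="session")
def default_bundle():
    """The reference study conditions: 20 peaks, ~5 features each, seed 1."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    b = default_bundle
    return run_pipeline(b.chromatograms, b.features, b.annotations,
                        network=b.network)
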