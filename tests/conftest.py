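import numpy as np
import pytest

from fuzzyhotspots import EFCMConfig, EventSet
from fuzzyhotspots.synth import generate_events, recovery_benchmark_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_events():
    """Four points on a unit square plus midpoint context, planar meters."""
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    return EventSet(points=pts, crs_tag="planar")


@pytest.fixture(scope="session")
def two_blob_run():
    """One converged EFCM run on the two-blob reference field (seed 7)."""
    from fuzzyhotspots import run_efcm

    cfg = recovery_benchmark_config(2, rng_seed=7)
    events, labels = generate_events(cfg)
    config = EFCMConfig(c0=6, rng_seed=7, radius_exponent_mode="half")
    return cfg, events, labels, run_efcm(events, config)
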