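import numpy as np
import pytest

from nirscalib import (
    PipelineConfig,
    SimulationConfig,
    build_packaged_phantom,
    run_all,
    run_simulation,
)

PIPELINE_SEED = 1
PIPELINE_PHOTONS = 100_000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def head1_phantom():
    return build_packaged_phantom(1)


@pytest.fixture(scope="session")
def head1_sim(head1_phantom):
    """One desk-scale simulation on head #1 at SDS 29 mm, shared by tests."""
    cfg = SimulationConfig(n_photons=PIPELINE_PHOTONS, seed=42)
    return run_simulation(head1_phantom, sds=29.0, config=cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full scaled-down pipeline: 8 heads x 11 SDS at 1e5 photons, fixed seed.

    Expensive (several minutes); session-scoped so the downstream surrogate
    and calibration checks share one run.
    """
    cfg = PipelineConfig(seed=PIPELINE_SEED, n_photons=PIPELINE_PHOTONS)
    return run_all(cfg)
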