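import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from crosstrait.pipeline import RunConfig
from crosstrait.synthetic import make_truth_config, simulate_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact planted-sharing bundle shared across tests (read-only)."""
    cfg = make_truth_config(n_traits=4, studies_per_trait=3, n_loci=12,
                            n_shared=4, n_shared_pairs=2, seed=7)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study-design bundle (10 traits / 40 studies / 60 loci)."""
    return simulate_bundle(make_truth_config(seed=11))


@pytest.fixture
def run_config():
    return RunConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
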