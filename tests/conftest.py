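import numpy as np
import pytest

from framefilter.core import RegionalTimeSeries
from framefilter.synth import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_ts(rng):
    """A well-behaved 30-frame, 6-node series."""
    return RegionalTimeSeries(data=rng.standard_normal((30, 6)))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature cohort for pipeline-level tests (fast to generate)."""
    cfg = SyntheticConfig(n_subjects=16, n_runs=2, T=100, N=16, seed=5)
    return generate(cfg)
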