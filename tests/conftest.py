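import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dscq
from dscq.phantom import (
    AcquisitionParams,
    COMPACT_ACQUISITION,
    default_truth_table,
    generate_study,
)
from dscq.pipeline import PipelineParams, quantify_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_table():
    return default_truth_table()


@pytest.fixture(scope="session")
def standard_study(truth_table):
    """Noise-free standard phantom (48x48x12, 60 timepoints at TR 1.5 s)."""
    return generate_study(
        AcquisitionParams(), truth_table, noise_sigma=0.0, seed=0, keep_concentration=True
    )


@pytest.fixture(scope="session")
def standard_result(standard_study):
    """Quantified noise-free standard phantom (shared, it is deterministic)."""
    return quantify_study(standard_study, PipelineParams())


@pytest.fixture(scope="session")
def compact_study(truth_table):
    """Small noisy phantom for fast per-test pipelines."""
    return generate_study(
        COMPACT_ACQUISITION, truth_table, noise_sigma=2.0, seed=5, keep_concentration=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
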