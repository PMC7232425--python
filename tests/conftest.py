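import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_table():
    """3 stations x 4 features with easy hand-checkable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 6.0, 8.0, 10.0], [0.0, 1.0, 0.0, 2.0]],
        index=["S1", "S2", "S3"],
        columns=["F1", "F2", "F3", "F4"],
    )


@pytest.fixture
def study_covariates():
    """Default-condition station table (20 stations, 4 regions)."""
    from driverscope import GeneratorConfig, generate_covariates

    return generate_covariates(GeneratorConfig(seed=5))
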