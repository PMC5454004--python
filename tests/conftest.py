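import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fxscreen as fx

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-conditions cohort shared across tests."""
    return fx.generate_cohort(fx.default_cohort_spec(n_per_group=25, seed=7))


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    lin = fx.profiles_to_frame(
        [fx.profile_transcript(t) for t in small_cohort.transcripts]
    )
    return fx.build_feature_table(
        lin, small_cohort.cognitive, small_cohort.labels
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
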