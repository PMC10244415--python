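import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small simulated cohort written to disk (shared across I/O tests)."""
    from catcycle.synthetic_data import SimConfig, write_cohort

    out = tmp_path_factory.mktemp("cohort")
    write_cohort(SimConfig(master_seed=11), out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
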