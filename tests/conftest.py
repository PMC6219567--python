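import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lncsubloc.fixtures import SyntheticSpec, generate_fixture_pwms, generate_transcripts
from lncsubloc.kmers import enumerate_kmers

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return enumerate_kmers(2, 5)


@pytest.fixture(scope="session")
def fixture_pwms():
    return generate_fixture_pwms(["AGCCC", "CTTCC", "GAGAG", "TTTGA"], softness=0.1)


@pytest.fixture(scope="session")
def small_bundle():
    """40 transcripts per class with planted AGCCC; fast enough for any test."""
    spec = SyntheticSpec(n_per_class=40, seed=7)
    records, truth = generate_transcripts(spec)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
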