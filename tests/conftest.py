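import numpy as np
import pytest

from capsleep import pipeline, synthetic
from capsleep.types import SignalRecord


@pytest.fixture(scope="session")
def small_config():
    """A 2-subject, 5-minute cohort: fast but structurally complete."""
    return synthetic.SyntheticConfig(duration_s=300.0, n_subjects=2, seed=42)


@pytest.fixture(scope="session")
def small_record(small_config):
    return synthetic.generate_record(small_config, 0)


@pytest.fixture(scope="session")
def prepared_record(small_record):
    record, _truth = small_record
    return pipeline.prepare_record(record)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gaussian_record(rng):
    return SignalRecord(samples=rng.normal(0.0, 20.0, 60_000), fs=100.0)
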