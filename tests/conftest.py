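import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from temporalcore.synth import SynthParams, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """Two subjects, four habitats, 30 daily timepoints at depth 2,000, with
    coupled palm dynamics — small enough for fast unit tests."""
    params = SynthParams(
        n_subjects=2, n_timepoints=30, seq_depth=2000,
        n_background_otus=40, palm_coupling=0.9, seed=11,
    )
    return generate_dataset(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_count_table(rng, n_otus, n_samples, p_zero=0.5, max_count=50):
    """Random sparse integer count matrix as a CountTable."""
    import pandas as pd

    from temporalcore.tables_io import CountTable

    counts = rng.integers(1, max_count, size=(n_otus, n_samples))
    counts[rng.random((n_otus, n_samples)) < p_zero] = 0
    return CountTable(pd.DataFrame(
        counts, index=[f"O{i}" for i in range(n_otus)],
        columns=[f"S{j}" for j in range(n_samples)]))
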