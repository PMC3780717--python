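import numpy as np
import pandas as pd
import pytest

from bucketeval import ExperimentMetadata, FitnessMatrix
from bucketeval.simulate import SyntheticConfig, generate_dataset


@pytest.fixture
def toy_fitness() -> FitnessMatrix:
    """Three experiments over three genes; e1 and e3 share the top gene."""
    frame = pd.DataFrame(
        {
            "e1": [9.0, 5.0, 4.0],
            "e2": [5.0, 9.0, 4.0],
            "e3": [8.0, 3.0, 5.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return FitnessMatrix(frame)


@pytest.fixture
def toy_metadata() -> ExperimentMetadata:
    table = pd.DataFrame(
        {"date": ["d1", "d1", "d2"], "compound": ["A", "B", "A"]},
        index=pd.Index(["e1", "e2", "e3"], name="experiment_id"),
    )
    return ExperimentMetadata(table)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Downscaled generator config usable in fast unit tests."""
    return SyntheticConfig(
        num_genes=1500,
        compounds=3,
        replicates_per_compound=4,
        num_dates=2,
        sensitive_set_size=40,
        batch_set_size=300,
        stress_set_size=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
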