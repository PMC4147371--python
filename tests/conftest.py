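import numpy as np
import pytest

from msimetab import pipeline, synthetic
from msimetab.config import PipelineConfig
from msimetab.study_design import build_manifest, load_cohort_table


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_table()


@pytest.fixture(scope="session")
def manifest11():
    """The full study layout: 11 subjects x 6 timepoints x 2 states."""
    return build_manifest(11)


@pytest.fixture(scope="session")
def small_config():
    """A reduced, noise-free study used for exact-recovery pipeline tests."""
    return PipelineConfig(n_subjects=2, n_features=12, baseline_sd=0.0,
                          seed=3)


@pytest.fixture(scope="session")
def zero_noise_dataset(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("dataset")
    return pipeline.simulate_dataset(small_config, out)


@pytest.fixture(scope="session")
def processed_dataset(zero_noise_dataset, small_config):
    return pipeline.process_dataset(zero_noise_dataset, small_config)


@pytest.fixture(scope="session")
def cohort_truth(manifest11):
    """Seeded full-size cohort ground truth with the default 55 features."""
    return synthetic.simulate_cohort(manifest11, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
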