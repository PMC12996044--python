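import numpy as np
import pandas as pd
import pytest

from mucopred import preprocess, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_responders=10, n_nonresponders=8, n_asvs=60,
        n_signal_asvs_nonresponse=2, n_signal_asvs_response=2,
        depth_range=(2_000, 4_000), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> simulate.CohortDataset:
    return simulate.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_relabund(small_cohort) -> pd.DataFrame:
    filtered = preprocess.filter_min_reads(small_cohort.counts)
    bacterial, _ = preprocess.exclude_nonbacterial(filtered,
                                                   small_cohort.taxonomy)
    return preprocess.relative_abundance(bacterial)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
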