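import warnings

import pytest
from hypothesis import settings

from harvestsel import SyntheticConfig, build_trait_table, generate_dataset

settings.register_profile("deterministic", derandomize=True, max_examples=200)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_bears_per_sex=8, years=(2015, 2016), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    ds = small_dataset
    return build_trait_table(ds.relocations, ds.activity, ds.roads, ds.bear_years)
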