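import numpy as np
import pandas as pd
import pytest

from cyclesem.simulate import GeneratorConfig, gen_full_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study conditions."""
    return gen_full_dataset(GeneratorConfig(), seed=1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset (fewer nests) for pipeline-level smoke tests."""
    cfg = GeneratorConfig(nests_per_year_mean=25.0, n_years=40)
    return gen_full_dataset(cfg, seed=77)


@pytest.fixture(scope="session")
def fitted_msem(default_dataset):
    """One MSEM fit shared by the tests that only inspect the posterior."""
    from cyclesem.msem import MultilevelSEM

    return MultilevelSEM(chains=2, draws=500, random_state=42).fit(
        default_dataset["nests"], default_dataset["between"])


@pytest.fixture(scope="session")
def fitted_rdsem(default_dataset):
    """One RDSEM fit shared across tests."""
    from cyclesem.rdsem import RDSEM, build_rdsem

    spec = build_rdsem(default_dataset["series"])
    return RDSEM(chains=2, draws=600, random_state=42).fit(spec)


@pytest.fixture()
def annual_counts():
    return pd.DataFrame({
        "year": [2000, 2001, 2002, 2003],
        "surveyed": [110, 110, 113, 113],
        "focal": [50, 40, 47, 30],
        "parid": [10, 10, 13, 13],
        "label": "A",
    })


def make_series(years, density, label="A"):
    return pd.DataFrame({
        "year": years,
        "surveyed": 100,
        "focal": np.asarray(density),
        "parid": 0,
        "label": label,
        "density_index": np.asarray(density, dtype=float),
    })
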