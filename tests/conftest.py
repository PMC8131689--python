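import numpy as np
import pandas as pd
import pytest

from cacaoflow import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """A short, coarse campaign: quick to generate, still diurnally shaped."""
    return sd.GeneratorConfig(seed=11, n_days=3, interval_min=5, n_flow_rows=1200)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return sd.generate_campaign(small_config)


@pytest.fixture(scope="session")
def default_campaign():
    """The study-scale campaign: 14 days, 1-min microclimate, 5556 rows/AF."""
    return sd.generate_campaign(sd.GeneratorConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def one_row_covariates(rh, ta, par, vpd, af):
    return pd.DataFrame(
        {"af": [af], "rh_a_pct": [rh], "t_a_c": [ta], "par_umol_m2_s": [par], "vpd_kpa": [vpd]}
    )
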