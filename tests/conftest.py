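import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import radpanel as rp
from radpanel import qpcr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_config():
    return rp.default_config(seed=42).with_noise(0.0)


@pytest.fixture(scope="session")
def noise_free_ct(noise_free_config):
    return rp.generate_ct_dataset(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_rel(noise_free_ct):
    mean_ct = qpcr.collapse_replicates(noise_free_ct)
    return qpcr.delta_ct(mean_ct, "ACTB")


@pytest.fixture(scope="session")
def default_ct():
    return rp.generate_ct_dataset(rp.default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def marker_dataset():
    """Default 40-observation marker table from the full pipeline."""
    from radpanel import pipeline as pl

    report = pl.run_full_pipeline(pl.RunConfig(seed=5))
    X = report.marker_data.drop(columns=["label"])
    y = report.marker_data["label"]
    return X, y
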