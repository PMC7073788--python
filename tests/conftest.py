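"""Shared fixtures.

Full-scale fixtures (177 samples x 13,435 retained channels) are session
scoped because generating them costs seconds; small-scale fixtures use a
coarser wavelength axis for speed.
"""

import numpy as np
import pytest

import libseed as ls


SMALL_R = 2000.0  # coarse resolving power: ~1,634 retained channels


def small_config(**kw):
    defaults = dict(resolving_power=SMALL_R, n_samples_per_cultivar=9)
    defaults.update(kw)
    return ls.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return ls.generate_dataset(small_config(), seed=101)


@pytest.fixture(scope="session")
def small_pre(small_dataset):
    return ls.preprocess_pipeline(small_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-scale dataset: 3 x 59 samples, 80 shots each."""
    return ls.generate_dataset(seed=101)


@pytest.fixture(scope="session")
def default_pre(default_dataset):
    return ls.preprocess_pipeline(default_dataset)


@pytest.fixture(scope="session")
def noiseless_pre():
    """Separable limit: every stochastic term off."""
    ds = ls.generate_dataset(ls.SimConfig().noiseless())
    return ls.preprocess_pipeline(ds)


@pytest.fixture(scope="session")
def split59():
    return ls.split_cal_pred(59, 3)
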