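import numpy as np
import pandas as pd
import pytest

from hopperdev import SimulationConfig, development_days


@pytest.fixture
def rng():
    return np.random.default_rng(20210738)


@pytest.fixture
def noiseless_config():
    """Study design with all noise switched off: outcomes sit on the model."""
    return SimulationConfig(seed=11, noise_sd_days=0.0, noise_sd_mass=0.0)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


def make_rearing_frame(c_dev, q10_dev, tvars, n_per_tvar, noise_sd, rng,
                       site="X", photoperiod="short", sex="female"):
    """A single-group rearing table generated from the development model."""
    tvar = np.repeat(np.asarray(tvars, float), n_per_tvar)
    d = development_days(c_dev, q10_dev, tvar)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, tvar.size)
    return pd.DataFrame(
        {"site": site, "photoperiod": photoperiod, "sex": sex,
         "tvar_c": tvar, "dev_days": d}
    )
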