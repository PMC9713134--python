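import numpy as np
import pytest

import vestigait as vg


@pytest.fixture(scope="session")
def noise_free_config() -> vg.SimConfig:
    return vg.SimConfig.noise_free(
        n_per_class=2, tasks=("GEC",), trials_per_task=1,
        placements=("l_arm", "lower_back", "l_foot", "r_foot"))


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_config):
    return vg.simulate_trial(noise_free_config, "H01", "GEC", 0)


@pytest.fixture(scope="session")
def default_noise_trial():
    cfg = vg.SimConfig(n_per_class=2, tasks=("GEC",), trials_per_task=1,
                       placements=("l_arm", "lower_back", "l_foot", "r_foot"),
                       seed=7)
    return vg.simulate_trial(cfg, "V01", "GEC", 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
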