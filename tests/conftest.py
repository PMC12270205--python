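import numpy as np
import pytest

from neurobag import net, synth


@pytest.fixture(scope="session")
def gen_params():
    return synth.GeneratorParams(seed=7)

@pytest.fixture(scope="session")
def small_cohort(gen_params):
    """40 CU + 4x10 impaired subjects with a few SAA-intermediate extras."""
    table, subjects = synth.generate_cohort(
        40, {g: 10 for g in synth.GROUPS_CI}, gen_params)
    return table, subjects


@pytest.fixture(scope="session")
def tiny_net_config():
    return net.NetConfig(stem_width=4, growth_rate=3, bottleneck_scale=2,
                         block_layers=(1, 1), final_conv_width=6,
                         compression=0.5)


@pytest.fixture(scope="session")
def tiny_model(tiny_net_config):
    return net.build_model(tiny_net_config, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(101)
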