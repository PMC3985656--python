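import numpy as np
import pytest

from g4ionx.core import tel23
from g4ionx.synthetic import ScenarioConfig, gen_titration


@pytest.fixture(scope="session")
def seq():
    return tel23()


@pytest.fixture()
def noiseless_titration():
    """Paired fa/fc titration series at the G22 preset constants, no noise."""
    return gen_titration(
        ScenarioConfig(seed=0, scenario="tel23_titration", noise_sd=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
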