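import numpy as np
import pytest

from ssclvoice import RunConfig, SimulationSpec, generate
from ssclvoice.datamodel import FAMILIES

ZERO_EFFECT = {f: 0.0 for f in FAMILIES}


def null_spec(seed: int, subject_effect_share: float = 0.25) -> SimulationSpec:
    """Zero-effect design: both classes drawn from one distribution."""
    return SimulationSpec(effect_size=dict(ZERO_EFFECT), parameter_effects={},
                          subject_effect_share=subject_effect_share, rng_seed=seed)


def separated_spec(seed: int = 7, shift: float = 4.0) -> SimulationSpec:
    """Strong class shift on the jitter and shimmer latent factors only."""
    eff = dict(ZERO_EFFECT)
    eff["jitter"] = eff["shimmer"] = shift
    return SimulationSpec(effect_size=eff, parameter_effects={}, rng_seed=seed)


@pytest.fixture(scope="session")
def default_table():
    """The default study-design table: 40+40 subjects x 3 records, 44 params."""
    return generate(SimulationSpec())


@pytest.fixture(scope="session")
def separated_table():
    return generate(separated_spec())


@pytest.fixture()
def config():
    return RunConfig(rng_seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
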