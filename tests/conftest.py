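import numpy as np
import pytest

from plcdiff import (DenoiserConfig, NoisePredictor, NoiseSchedule, ToySpec,
                     make_toy_complex)
from plcdiff.nn import perturb_parameters


@pytest.fixture(scope="session")
def schedule():
    return NoiseSchedule()


@pytest.fixture(scope="session")
def toy():
    """A small helix + 3-atom ligand system with one conformer."""
    return make_toy_complex(ToySpec(n_res=8, n_lig=3, pocket_jitter=0.5, seed=2))


SMALL_CONFIG = DenoiserConfig(n_blocks=1, c_s=16, c_p=8, n_heads=2,
                              c_outer=4, c_tri=4, n_rbf=16, time_dim=8)


@pytest.fixture(scope="session")
def small_model():
    """Desk-scale model with randomized (non-zero) output projections."""
    model = NoisePredictor(SMALL_CONFIG, seed=0)
    perturb_parameters(model, np.random.default_rng(0), 0.05)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
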