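import numpy as np
import pytest

from depotpk.biopsy import design_it_mouse
from depotpk.kinetics import ReleaseModel

SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def noise_free_it_design():
    """The intratumoral mouse design with all noise switched off."""
    return design_it_mouse(recovery_cv=0.0, signal_cv=0.0, seed=SEED)


@pytest.fixture
def it_design():
    """The intratumoral mouse design at its default 10% CVs."""
    return design_it_mouse(seed=SEED)


@pytest.fixture
def release_63h():
    return ReleaseModel.from_half_life(63.0)
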