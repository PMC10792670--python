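import numpy as np
import pytest

from iris_elucidate.biotransform import DGSM_SMILES
from iris_elucidate.chem import default_mass_shift_library


@pytest.fixture(scope="session")
def dgsm_smiles() -> str:
    return DGSM_SMILES


@pytest.fixture(scope="session")
def shift_library():
    return default_mass_shift_library()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231220)
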