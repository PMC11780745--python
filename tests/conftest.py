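import numpy as np
import pytest

from spincouple import ModelParams, SystemSpec


@pytest.fixture(scope="session")
def cubane_params() -> ModelParams:
    """Three-site S=3/2 couplings of the trimanganese cubane model
    (CASSCF-derived ferromagnetic regime), in cm^-1."""
    return ModelParams.from_pairs(
        3, {(0, 1): -6.6, (0, 2): -27.7, (1, 2): -20.0}, b=-0.01)


@pytest.fixture(scope="session")
def chain33_specs() -> list[SystemSpec]:
    """All total-spin blocks of the three-site, three-electron chain."""
    return [SystemSpec.equal_chain(3, 3, f"{ts}/2") for ts in (1, 3, 5, 7, 9)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
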