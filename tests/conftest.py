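import numpy as np
import pytest

from dissolvox import Compound, GenerationParams
from dissolvox.synthetic_data import ETHYL_CELLULOSE, THEOPHYLLINE


@pytest.fixture
def api() -> Compound:
    return THEOPHYLLINE


@pytest.fixture
def excipient() -> Compound:
    return ETHYL_CELLULOSE


@pytest.fixture
def compounds(api, excipient) -> list[Compound]:
    return [api, excipient]


@pytest.fixture
def unwettable_excipient() -> Compound:
    # matrix former with the measured (un-adjusted) contact angle
    return Compound(
        id=31, name="ethyl cellulose (unwettable)", density=1139.9,
        solubility=0.0, contact_angle=93.2,
    )


@pytest.fixture
def small_params() -> GenerationParams:
    """A few-mm cylinder holding a couple thousand voxels; runs in ms."""
    return GenerationParams(
        shape=(12, 20, 20),
        voxel_edge=0.2,
        diameter=3.5,
        height=2.2,
        target_masses={1: 2.0, 31: 4.0},
        mode="distributed",
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
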