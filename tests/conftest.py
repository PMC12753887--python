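import numpy as np
import pytest

from cordsim import (
    AtrophySpec,
    PhantomParams,
    SimulationRecipe,
    generate_phantom,
    simulate_atrophy,
)


@pytest.fixture(scope="session")
def phantom():
    """Default synthetic template: (volume, cord mask, landmark table)."""
    return generate_phantom(PhantomParams())


@pytest.fixture(scope="session")
def baseline(phantom):
    """Atrophy-free pipeline output (the reference arm of every comparison)."""
    vol, mask, _ = phantom
    out, soft_mask, _ = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(0.0)))
    return out, soft_mask


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
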