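from __future__ import annotations

import numpy as np
import pytest

from topotest.phantom import Parcellation, PhantomConfig, pseudorandom_volume, synth_parcellation
from topotest.volume_io import MaskedVolume


@pytest.fixture(scope="session")
def small_parc() -> Parcellation:
    """30-region Voronoi parcellation on a 20x24x20 grid (~4300 mask voxels)."""
    return synth_parcellation((20, 24, 20), K=30, seed=1)


@pytest.fixture(scope="session")
def medium_parc() -> Parcellation:
    """116-region parcellation on the 40x48x40 test grid."""
    return synth_parcellation((40, 48, 40), K=116, seed=1)


@pytest.fixture()
def small_pattern(small_parc) -> MaskedVolume:
    return pseudorandom_volume(small_parc, PhantomConfig(seed=3))


def full_mask_volume(data: np.ndarray) -> MaskedVolume:
    data = np.asarray(data, dtype=float)
    return MaskedVolume(data=data, mask=np.ones(data.shape, dtype=bool))
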