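import numpy as np
import pytest

from hubspoke.core import CONDITIONS, VolumeGrid
from hubspoke.glm import BetaPattern
from hubspoke.mvpa import zscore_patterns
from hubspoke.phantom import (
    AtlasConfig,
    RegionSpec,
    Role,
    make_phantom_atlas,
    make_phantom_truth,
    small_atlas_config,
)


def tiny_atlas_config() -> AtlasConfig:
    """A 12^3 atlas small enough for exhaustive-oracle tests."""
    return AtlasConfig(
        grid_shape=(12, 12, 12),
        brain_semiaxes_mm=(9.0, 9.0, 8.0),
        regions={
            Role.SEMANTIC_HUB: RegionSpec((-4.0, -4.0, 0.0), 30),
            Role.MODALITY_REGION: RegionSpec((4.0, 4.0, 0.0), 30),
            Role.AUDITORY_SPOKE: RegionSpec((-4.0, 4.0, 0.0), 15),
            Role.VISUAL_SPOKE: RegionSpec((4.0, -4.0, 0.0), 15),
            Role.WHITE_MATTER: RegionSpec((10.0, 10.0, 0.0), 25),
            Role.CSF: RegionSpec((-10.0, -10.0, 0.0), 20),
        },
        # small territories so truth construction fits the tiny brain
    )


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_phantom_atlas(tiny_atlas_config())


@pytest.fixture(scope="session")
def small_atlas():
    return make_phantom_atlas(small_atlas_config())


@pytest.fixture(scope="session")
def small_truth(small_atlas):
    return make_phantom_truth(small_atlas, seed=7)


def random_patterns(
    shape=(4, 4, 4), n_runs: int = 4, seed: int = 0, zscore: bool = True
) -> BetaPattern:
    """Label-independent random beta patterns (the classification null)."""
    rng = np.random.default_rng(seed)
    grid = VolumeGrid.centered(shape)
    data = rng.standard_normal((n_runs, len(CONDITIONS), *shape))
    pattern = BetaPattern(
        data=data,
        conditions=list(CONDITIONS),
        grid=grid,
        mask=np.ones(shape, dtype=bool),
    )
    return zscore_patterns(pattern) if zscore else pattern
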