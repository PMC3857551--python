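import numpy as np
import pytest

from coactnet.maimage import VolumeGrid, stack_corpus
from coactnet.synthcorpus import SynthConfig, build_corpus


@pytest.fixture(scope="session")
def coarse_grid():
    """8 mm grid: ~7k in-mask voxels, fast enough for every unit test."""
    return VolumeGrid.talairach(spacing=8.0)


@pytest.fixture(scope="session")
def fast_grid():
    """4 mm analysis grid (the default study resolution)."""
    return VolumeGrid.talairach(spacing=4.0)


@pytest.fixture(scope="session")
def small_corpus(coarse_grid):
    """k=4 single-blob corpus on the coarse grid."""
    cfg = SynthConfig(k_networks=4, e_experiments=120, seed=101)
    return build_corpus(cfg, coarse_grid)


@pytest.fixture(scope="session")
def small_ma(small_corpus, coarse_grid):
    return stack_corpus(small_corpus, coarse_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
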