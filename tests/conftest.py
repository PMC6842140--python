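import numpy as np
import pytest

from rnascout import SelectionParams, TileIndex
from rnascout.simulate import ArchiveConfig, build_archive


@pytest.fixture
def tiny_tiles():
    return TileIndex([("chr1", 10_000)], tile_size=5000)


@pytest.fixture
def default_params():
    return SelectionParams()


@pytest.fixture(scope="session")
def small_archive():
    """10-run archive (2 low-alignability) on a 300 kb genome."""
    config = ArchiveConfig(
        seed=3, n_runs=10, n_genes=50, genome_length=300_000,
        spots_per_run=5000, bad_run_fraction=0.2,
    )
    return build_archive(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
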