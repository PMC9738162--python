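import numpy as np
import pytest

from ovprofiler.grid import build_bin_grid
from ovprofiler.simulate import SimConfig


SMALL_GENOME = [("chr1", 12_000_000), ("chr2", 9_000_000), ("chr17", 9_000_000)]
SMALL_LOCUS = ("chr17", 6_000_000, 6_400_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SimConfig(
        n_patients=8,
        genome=list(SMALL_GENOME),
        ccne1_locus=SMALL_LOCUS,
        seed=42,
    )


@pytest.fixture
def small_grid(small_config):
    return small_config.build_grid()


@pytest.fixture
def flat_grid():
    """600-bin single-chromosome grid with benign annotations."""
    g = build_bin_grid([("chr1", 12_000_000)], 20_000, rng=7,
                       blacklist_fraction=0.0, low_mappability_fraction=0.0)
    g.mappability[:] = 1.0
    return g
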