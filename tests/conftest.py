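import numpy as np
import pytest

from abc_evolve.io_formats import RunConfig

CHROMS = {"chr1": 30_000_000, "chr2": 20_000_000, "chr3": 12_000_000}


@pytest.fixture
def chrom_lengths():
    return dict(CHROMS)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
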