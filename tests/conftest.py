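import numpy as np
import pytest

from evoseg.genome import Genome, GenomeBounds, default_catalog


@pytest.fixture
def bounds():
    return GenomeBounds()


@pytest.fixture
def catalog():
    return default_catalog()


@pytest.fixture
def winner_genome():
    """The depth-4 architecture the full-scale search selects."""
    return Genome(dropout_rate=0.1464, filters=(16, 64, 128, 256), depth=4,
                  use_skip=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
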