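import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from estssr.sequence_io import Contig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def random_contigs(rng):
    def make(n, length):
        return [
            Contig(id=f"r{i}", seq=random_seq(rng, length)) for i in range(n)
        ]

    return make
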