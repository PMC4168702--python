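import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from under2.readset import ReadSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_pair():
    """The worked hand-example pair (forward-only comparisons)."""
    return ReadSet("r1", ["ACGTT"]), ReadSet("r2", ["ACGAA", "CGTTC"])


def random_readset(rng, label, n_reads=(2, 7), length=(8, 25)) -> ReadSet:
    reads = [
        "".join(rng.choice(list("ACGT"), rng.integers(*length)))
        for _ in range(rng.integers(*n_reads))
    ]
    return ReadSet(label, reads)
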