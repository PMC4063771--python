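import numpy as np
import pytest

from snoevo.simulate import default_root_snorna


@pytest.fixture(scope="session")
def canonical_gene():
    """A canonical 82-nt snoRNA with its structural annotation."""
    seq, ann = default_root_snorna(seed=0)
    return seq, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
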