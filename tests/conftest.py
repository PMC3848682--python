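import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bloomdbg.kmer_core import canonical_array, kmers_of_sequence
from bloomdbg.kmer_counting import SolidKmerList

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def _solid_from_sequence(seq: str, k: int) -> SolidKmerList:
    """Node set of a sequence: sorted unique canonical k-mers."""
    vals = np.unique(canonical_array(kmers_of_sequence(seq, k), k))
    return SolidKmerList(vals, k=k)


@pytest.fixture
def solid_from_sequence():
    return _solid_from_sequence


@pytest.fixture
def random_genome():
    """Deterministic uniform genome of a requested length."""

    def make(length: int, seed: int) -> str:
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))

    return make
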