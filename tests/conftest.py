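import numpy as np
import pytest

from premirscan.datasets import Dataset, HairpinRecord
from premirscan.simulate import FixtureSpec, make_hairpin_sequences


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def small_hairpin_sets() -> tuple[Dataset, Dataset]:
    """30 designed stem-loops and 30 shuffled negatives (46 nt each)."""
    return make_hairpin_sequences(FixtureSpec(seed=7, n_pos=30, n_neg=30))


@pytest.fixture(scope="session")
def folded_positives(small_hairpin_sets) -> list[HairpinRecord]:
    pos, _ = small_hairpin_sets
    return [r.folded() for r in pos.records]
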