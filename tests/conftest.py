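import numpy as np
import pytest

from iqdfam.io import SequenceRecord
from iqdfam.promoter import CisElement

# non-palindromic, mutually non-matching consensi used across promoter tests
TEST_LIBRARY = [
    CisElement("E_DROUGHT_A", "TTGACC", "synthetic drought-like element"),
    CisElement("E_DROUGHT_B", "CACGTA", "synthetic drought-like element"),
    CisElement("E_WOUND", "CCGAAA", "synthetic wound-like element"),
]


@pytest.fixture(scope="session")
def test_library():
    return TEST_LIBRARY


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=n))


@pytest.fixture
def make_records():
    def _make(seqs, prefix="s"):
        return [
            SequenceRecord(f"{prefix}{i}", f"{prefix}{i}", s)
            for i, s in enumerate(seqs)
        ]
    return _make
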