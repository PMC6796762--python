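import numpy as np
import pytest

from sixma.seqio import CENTER_INDEX, WINDOW_LENGTH, LabeledDataset, SequenceRecord

BASES = "ACGT"


def random_window(rng: np.random.Generator) -> str:
    """A random valid 41-nt window with the central adenine."""
    chars = [BASES[i] for i in rng.integers(0, 4, size=WINDOW_LENGTH)]
    chars[CENTER_INDEX] = "A"
    return "".join(chars)


def random_dataset(rng: np.random.Generator, n_pos: int, n_neg: int) -> LabeledDataset:
    recs = [
        SequenceRecord(id=f"p{i}", seq=random_window(rng), label=1)
        for i in range(n_pos)
    ] + [
        SequenceRecord(id=f"n{i}", seq=random_window(rng), label=0)
        for i in range(n_neg)
    ]
    return LabeledDataset(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def labeled300():
    """300 random labeled windows (enough for the KNN reference)."""
    return random_dataset(np.random.default_rng(7), 150, 150)
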