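import numpy as np
import pytest

from qaenc.corpus import QuestionBank, Transcript, Word, load_qa35
from qaenc.synthetic import generate_synthetic_corpus


@pytest.fixture(scope="session")
def qa35() -> QuestionBank:
    return load_qa35()


@pytest.fixture
def small_bank() -> QuestionBank:
    return QuestionBank(
        tuple((f"q{i}", f"Does the input mention topic {i}?") for i in range(6))
    )


@pytest.fixture
def tiny_transcript() -> Transcript:
    words = [
        Word("the", 0.0, 0.2), Word("dog", 0.25, 0.5), Word("ran", 0.55, 0.8),
        Word("up", 0.85, 1.0), Word("the", 1.05, 1.2), Word("mountain", 1.25, 1.7),
    ]
    return Transcript("tiny", tuple(words))


@pytest.fixture
def small_corpus(small_bank):
    """Synthetic themed corpus with gold annotations and keyword annotator."""
    return generate_synthetic_corpus(
        small_bank, n_words=400, window_positive_rate=0.25, seed=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
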