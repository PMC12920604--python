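import random

import pytest

from pedsleep.matcher import compile_matcher
from pedsleep.vocabulary import load_vocabulary

# words that are not bank surfaces and cannot combine with them into one
# (checked implicitly by the oracle-equivalence tests, which compare two
# independent matchers rather than assuming anything about the filler)
FILLER_WORDS = [
    "patient", "mother", "father", "school", "today", "visit", "reports",
    "denies", "history", "exam", "normal", "review", "plan", "continue",
    "daily", "weight", "height", "chart", "clinic", "follow",
]


@pytest.fixture(scope="session")
def dse_vocab():
    return load_vocabulary("dse")


@pytest.fixture(scope="session")
def dse_matcher(dse_vocab):
    return compile_matcher(dse_vocab)


@pytest.fixture(scope="session")
def all_surfaces(dse_vocab):
    return [e.surface for e in dse_vocab.entries() if e.kind == "literal"]


def make_random_texts(surfaces, n_texts, seed, max_pieces=12):
    """Random concatenations of bank surfaces and filler words.

    Pieces are joined with varied separators to exercise normalization.
    """
    rng = random.Random(seed)
    seps = [" ", "  ", ", ", ". ", "-", "\n", "!! "]
    texts = []
    for _ in range(n_texts):
        k = rng.randint(0, max_pieces)
        pieces = []
        for _ in range(k):
            if rng.random() < 0.5:
                pieces.append(rng.choice(surfaces))
            else:
                pieces.append(rng.choice(FILLER_WORDS))
        out = []
        for p in pieces:
            out.append(p.upper() if rng.random() < 0.15 else p)
            out.append(rng.choice(seps))
        texts.append("".join(out))
    return texts
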