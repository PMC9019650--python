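import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stereotrend import Document, TargetLexicon, ValenceLexicon, tokenize_corpus


@pytest.fixture
def targets():
    return TargetLexicon.from_pairs(
        age_terms=("elderly", "old people", "senior citizen"),
        role_terms=("grandma", "grandparent"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


def random_documents(rng, n_docs=8, targets=None, mean_tokens=400):
    """Random corpora mixing filler, articles, and single/multiword target
    terms, for oracle-equivalence checks."""
    vocab = [f"w{i}" for i in range(30)]
    articles = ["the", "a", "an"]
    term_words = ["elderly", "old", "people", "senior", "citizen", "grandma", "grandparent"]
    choices = vocab + articles * 4 + term_words * 3
    docs = []
    for d in range(n_docs):
        n_sent = int(rng.integers(3, 12))
        sents = []
        for _ in range(n_sent):
            length = int(rng.integers(1, max(2, 2 * mean_tokens // (10 * n_sent))))
            toks = [choices[int(rng.integers(0, len(choices)))] for _ in range(length)]
            sents.append(" ".join(toks) + ".")
        year = int(rng.integers(1810, 2020))
        genre = ["fiction", "newspapers"][int(rng.integers(0, 2))]
        docs.append(Document(doc_id=f"r{d}", year=year, genre=genre, text=" ".join(sents)))
    return docs


@pytest.fixture
def random_corpus(rng, targets):
    docs = random_documents(rng)
    return tokenize_corpus(docs)


@pytest.fixture
def flat_lexicon():
    """Every oracle-corpus word rated; targets' component words included."""
    words = (
        [f"w{i}" for i in range(30)]
        + ["old", "people", "senior", "citizen", "elderly", "grandma", "grandparent"]
    )
    return ValenceLexicon({w: (3.0, 3.0) for w in words})
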