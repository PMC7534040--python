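import numpy as np
import pytest

import semcoh as sc


@pytest.fixture(scope="session")
def small_topics():
    """Compact ring topic model shared across tests (5 disjoint topics)."""
    spec = sc.TopicModelSpec(
        n_topics=5, vocab_per_topic=40, shared_vocab=0, seed=11
    )
    return sc.build_topics(spec)


@pytest.fixture(scope="session")
def small_space(small_topics):
    corpus, _ = sc.gen_corpus(small_topics, n_docs=60, doc_length=80, seed=12)
    return sc.build_space(corpus, d=20)


@pytest.fixture(scope="session")
def study_topics():
    """Default-scale ring topic model with neighbour sharing."""
    return sc.build_topics(sc.TopicModelSpec(seed=1))


@pytest.fixture(scope="session")
def study_space(study_topics):
    corpus, _ = sc.gen_corpus(study_topics, n_docs=400, doc_length=150, seed=2)
    return sc.build_space(corpus, d=100)


@pytest.fixture(scope="session")
def identity_space():
    """Hand-made space with orthonormal word vectors (easy exact oracles)."""
    words = ["apple", "banana", "cherry", "date"]
    return sc.SemanticSpace(
        vocabulary=words,
        vectors=np.eye(4),
        weighting="raw",
        d=4,
    )
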