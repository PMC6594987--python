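"""Shared fixtures: synthetic corpora and trained taggers.

Model training is expensive, so trained models are session-scoped and every
test that needs one reuses the same instance.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from curatext import crf_tagger as C
from curatext import evaluation as E
from curatext import neural_tagger as N
from curatext.synthetic_fixtures import (
    GeneratorConfig,
    bio_sentences,
    generate_corpus,
)

ENTITY = "BrainRegion"


def featurize(tokens):
    return C.build_features(tokens)


@pytest.fixture(scope="session")
def synthetic_corpus():
    return generate_corpus(GeneratorConfig(seed=5, n_documents=40,
                                           sentences_per_document=5))


@pytest.fixture(scope="session")
def corpus_split(synthetic_corpus):
    """(train, test, validate) BIO sentences for the brain-region type."""
    sents = bio_sentences(synthetic_corpus, ENTITY)
    return E.split_corpus(sents, (0.70, 0.15, 0.15), seed=3)


@pytest.fixture(scope="session")
def crf_model(corpus_split):
    train_set, _, _ = corpus_split
    return C.train([(featurize(t), l) for t, l in train_set], ENTITY, seed=1)


@pytest.fixture(scope="session")
def tiny_crf():
    """A CRF trained on two short sentences — cheap potentials for
    decoding-oracle and property tests."""
    data = []
    for text, labels in [
        ("the ventral nucleus was large", ["O", "B", "I", "O", "O"]),
        ("cells fired in the dorsal cortex", ["O", "O", "O", "O", "B", "I"]),
    ]:
        from curatext.corpus_io import tokenize
        toks = tokenize(text)
        labs = [l if l == "O" else f"{l}-{ENTITY}" for l in labels]
        data.append((featurize(toks), labs))
    return C.train(data, ENTITY, C.CRFConfig(max_iterations=80), seed=0)


@pytest.fixture(scope="session")
def nn_config():
    # scaled-down architecture: same topology, smaller dimensions
    return N.NetConfig(epochs=8, batch_size=10, char_embed_dim=12,
                       word_embed_dim=24, char_word_dim=24,
                       word_hidden_dim=24, dropout=0.5,
                       learning_rate=0.013, seed=2)


@pytest.fixture(scope="session")
def nn_model(corpus_split, nn_config):
    train_set, _, _ = corpus_split
    data = [([t.surface for t in toks], labs) for toks, labs in train_set]
    return N.train(data, ENTITY, nn_config)


def random_model_like(model: C.TaggerModel, seed: int) -> C.TaggerModel:
    """Clone a CRF with randomized weights — an arbitrary valid model for
    decoding property tests."""
    rng = np.random.default_rng(seed)
    return C.TaggerModel(
        entity_type=model.entity_type,
        feature_index=model.feature_index,
        weights=rng.normal(0, 1, model.weights.shape),
        transitions=rng.normal(0, 1, model.transitions.shape),
        config=model.config,
        seed=seed,
    )
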