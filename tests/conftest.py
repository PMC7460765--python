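"""Shared fixtures: synthetic corpora and small trained models.

Heavy objects (trained translators) are session-scoped so the acceptance
checks and unit tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemnmt import (
    ParallelCorpus,
    build_vocabulary,
    split_corpus,
)
from chemnmt import neural_models as nn
from chemnmt.synth_nomenclature import SyntheticGrammar, generate_corpus


@pytest.fixture(scope="session")
def grammar() -> SyntheticGrammar:
    return SyntheticGrammar()


@pytest.fixture(scope="session")
def corpus3000(grammar):
    return generate_corpus(grammar, 3000, seed=1)


@pytest.fixture(scope="session")
def split3000(corpus3000):
    return split_corpus(corpus3000, 0.2, seed=1)


@pytest.fixture(scope="session")
def vocab3000(corpus3000):
    return build_vocabulary(corpus3000)


@pytest.fixture(scope="session")
def tiny_corpus(split3000):
    """Ten pairs for memorization checks."""
    train_set, _ = split3000
    return ParallelCorpus(train_set.pairs[:10], train_set.direction)


@pytest.fixture(scope="session")
def small_corpus(grammar):
    """A 120-pair corpus for fast unit-level checks."""
    return generate_corpus(grammar, 120, seed=7)


@pytest.fixture(scope="session")
def lstm_curve(split3000, vocab3000):
    """LSTM translators trained at growing training-set sizes.

    Returns (sizes, exact-match rates, results at the largest size, test
    set): the learnability curve on held-out compositions of seen
    morphemes.
    """
    train_set, test_set = split3000
    sizes = (500, 1500, len(train_set))
    exact = []
    final_results = None
    for n_train in sizes:
        sub = ParallelCorpus(train_set.pairs[:n_train], train_set.direction)
        cfg = nn.TrainConfig(
            batch_size=64, epochs=30, latent_dim=128, seed=1, validation_fraction=0.0
        )
        model = nn.build_lstm_translator(vocab3000, cfg)
        nn.train(model, sub, cfg)
        results = nn.translate_many(model, [p.source_name for p in test_set])
        exact.append(
            sum(r.output == p.target_name for r, p in zip(results, test_set))
            / len(test_set)
        )
        final_results = results
    return sizes, exact, final_results, test_set


@pytest.fixture(scope="session")
def memorized_models(tiny_corpus):
    """Both architectures trained to convergence on the ten-pair corpus."""
    vocab = build_vocabulary(tiny_corpus)
    models = {}
    for arch in ("LSTM", "CNN"):
        cfg = nn.TrainConfig(
            batch_size=10, epochs=0, latent_dim=64, seed=0, validation_fraction=0.0
        )
        model = nn.build_translator(arch, vocab, cfg)
        nn.train_to_accuracy(model, tiny_corpus)
        models[arch] = model
    return models
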