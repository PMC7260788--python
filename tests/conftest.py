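"""Shared fixtures: toy corpora and session-scoped trained models.

Training the tiny models is the expensive part of the suite, so the trained
decorators and scaffold generator are built once per session and shared by
the model, sampling and acceptance tests.
"""

import numpy as np
import pytest

from scaffdec.fixtures import FixtureSpec, make_toy_corpus, tiny_model_preset
from scaffdec.model import train_decorator, train_scaffold_generator


@pytest.fixture(scope="session")
def toy_corpus10():
    return make_toy_corpus(FixtureSpec(n_molecules=10))


@pytest.fixture(scope="session")
def toy_corpus60():
    return make_toy_corpus(FixtureSpec(n_molecules=60))


@pytest.fixture(scope="session")
def tuple_dataset10(toy_corpus10):
    return toy_corpus10.truth_dataset()


@pytest.fixture(scope="session")
def trained_multi(tuple_dataset10):
    """Tiny multi-step decorator overfit on the 10-tuple fixture."""
    preset = tiny_model_preset()
    model, trace = train_decorator(tuple_dataset10, mode="multi",
                                   epochs=preset.epochs, rng_seed=42,
                                   lr=preset.lr)
    return model, trace


@pytest.fixture(scope="session")
def trained_single(tuple_dataset10):
    """Tiny single-step decorator overfit on the 10-tuple fixture."""
    preset = tiny_model_preset()
    model, trace = train_decorator(tuple_dataset10, mode="single",
                                   epochs=400, rng_seed=42, lr=preset.lr)
    return model, trace


@pytest.fixture(scope="session")
def trained_scaffold_generator(toy_corpus60):
    scaffolds = sorted({gt.scaffold for gt in toy_corpus60.truth})
    model, trace = train_scaffold_generator(scaffolds, epochs=200, rng_seed=0,
                                            lr=5e-3)
    return model, trace, scaffolds
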