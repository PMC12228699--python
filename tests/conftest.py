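"""Shared fixtures: small synthetic datasets and trained models.

Everything is generated programmatically with fixed seeds; the expensive
fixtures (trained models) are session-scoped.
"""

from __future__ import annotations

import pytest

from chemtaste.classifiers.base import TrainConfig, train
from chemtaste.curation import split_dataset
from chemtaste.synthetic import RuleSet, generate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """600 zero-noise rule-labeled molecules."""
    return generate_dataset(600, RuleSet(), seed=42)


@pytest.fixture(scope="session")
def clean_split(clean_dataset):
    return split_dataset(clean_dataset, test_fraction=0.15, seed=7)


@pytest.fixture(scope="session")
def token_model(clean_split):
    """Small token model trained to high accuracy on the clean train split."""
    config = TrainConfig(backend="token_lm", learning_rate=1e-2, epochs=12, seed=0)
    return train(clean_split.train, config)


@pytest.fixture(scope="session")
def gbt_model(clean_split):
    config = TrainConfig(backend="gbt", seed=0)
    return train(clean_split.train, config)


@pytest.fixture(scope="session")
def smiles_pool(clean_dataset):
    """Canonical SMILES of the clean dataset, for fuzzing."""
    return sorted({r.canonical_smiles for r in clean_dataset})
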