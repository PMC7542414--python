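"""Shared fixtures: seeded synthetic datasets and a default project config."""

from __future__ import annotations

import pytest

import binlink as bl


@pytest.fixture(scope="session")
def config() -> bl.LinkageConfig:
    return bl.default_config(secret_key=b"test-project-key")


@pytest.fixture(scope="session")
def small_dataset():
    """~350-record dataset with heavy duplication and the high-error preset."""
    records, truth = bl.generate_dataset(120, seed=7)
    return records, truth


@pytest.fixture(scope="session")
def small_encoded(small_dataset, config):
    records, _ = small_dataset
    return bl.encode_dataset(records, config.bloom_params, config.strategies)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-error duplicates: every duplicate is field-identical to its base."""
    model = bl.default_error_model().scaled(0.0)
    records, truth = bl.generate_dataset(
        80, dup_dist=bl.DuplicateDistribution("fixed", {"count": 2}),
        model=model, seed=11)
    return records, truth


@pytest.fixture(scope="session")
def clean_encoded(clean_dataset, config):
    records, _ = clean_dataset
    return bl.encode_dataset(records, config.bloom_params, config.strategies)
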