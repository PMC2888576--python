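"""Shared fixtures: configs and generated bundles reused across test modules."""
from __future__ import annotations

import warnings

import pytest

from atexpand import GeneratorConfig, generate_expression, generate_phenotypes
from atexpand.preprocess import filter_genes, quantile_normalize


def small_gene_counts() -> dict[str, int]:
    """A reduced gene universe for fast Monte-Carlo loops."""
    return {
        "ATE": 10, "HFD_INDUCED": 8, "LUN_INDUCED": 8,
        "DEV_EARLY": 8, "MATERNAL_HFD": 8, "FLAT": 60,
    }


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def phenotypes(default_config):
    return generate_phenotypes(default_config)


@pytest.fixture(scope="session")
def bundle(default_config, phenotypes):
    return generate_expression(default_config, phenotypes)


@pytest.fixture(scope="session")
def normalized(bundle):
    return quantile_normalize(bundle.matrix)


@pytest.fixture(scope="session")
def filter_report(normalized):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return filter_genes(normalized)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, n_genes_per_class=small_gene_counts())
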