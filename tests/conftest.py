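"""Shared fixtures: tiny hand-built datasets and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cssig.data_model import ExpressionDataset, GeneModule, MetaboliteTable
from cssig.synthetic_data import GeneratorConfig, generate_collection

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 genes x 4 samples with hand-checkable structure."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],   # GA: increasing
            [2.0, 4.0, 6.0, 8.0],   # GB: GA scaled (r = 1 with GA)
            [4.0, 3.0, 2.0, 1.0],   # GC: reversed (r = -1 with GA)
            [1.0, 2.0, 2.0, 4.0],   # GD
        ],
        index=["GA", "GB", "GC", "GD"],
        columns=["S1", "S2", "S3", "S4"],
    )
    annotations = pd.DataFrame(
        {"tissue_class": ["normal", "normal", "cancer_low_grade",
                          "cancer_high_grade"]},
        index=values.columns,
    )
    return ExpressionDataset("tiny", values, annotations)


@pytest.fixture
def tiny_metabolites() -> MetaboliteTable:
    values = pd.DataFrame(
        [[1.0, 3.0, 2.0, 4.0], [2.0, 2.0, 3.0, 5.0]],
        index=["citrate", "spermine"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return MetaboliteTable(values)


def small_config(**overrides) -> GeneratorConfig:
    """A scaled-down generator config for fast unit tests."""
    defaults = dict(
        n_datasets=3,
        n_genes=400,
        samples_per_class={"normal": 10, "cancer_low_grade": 15,
                           "cancer_high_grade": 15, "metastasis": 5,
                           "stroma": 5},
        planted_size=40,
        stroma_size=25,
        n_decoys=10,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across read-only tests."""
    collection, metabolites, truth = generate_collection(small_config(), seed=11)
    return collection, metabolites, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
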