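"""Shared fixtures: synthetic datasets and trained systems.

The expensive artefacts (the default 360-compound clearance dataset, the
fu,p-benefit study, one trained two-step system on a reduced dataset) are
session-scoped so every test that needs them shares a single computation.
"""

from dataclasses import replace
from types import SimpleNamespace

import pytest

from renalxcrete.synthetic import (
    SyntheticConfig,
    generate_descriptor_matrix,
    generate_pk_table,
)
from renalxcrete.two_step import SystemConfig, fup_benefit_study, train_system

#: Seed for the default synthetic study dataset used across the suite.
DATASET_SEED = 11

#: Reduced forest sizes for the recovery experiments; the statistical
#: behaviour is indistinguishable from the full-size defaults on these
#: problem sizes while keeping repeated training runs cheap.
FAST_FIT = dict(boruta_trees=100, boruta_max_iter=20, rf_trees=150)


@pytest.fixture(scope="session")
def clr_dataset():
    """Default-composition clearance dataset (94 R / 86 IM / 180 S) with
    planted descriptors; stored CR-type labels stripped so training derives
    them."""
    config = SyntheticConfig(seed=DATASET_SEED)
    records, truth = generate_pk_table(config)
    matrix = generate_descriptor_matrix(records, config, truth)
    records = [replace(r, cr_type=None) for r in records]
    return SimpleNamespace(config=config, records=records, truth=truth, matrix=matrix)


@pytest.fixture(scope="session")
def benefit_results(clr_dataset):
    """Per-type regression with vs without fu,p over 5 matched splits."""
    config = SystemConfig(seed=0, fup_source="observed", **FAST_FIT)
    return fup_benefit_study(
        clr_dataset.records,
        clr_dataset.matrix,
        config,
        split_seeds=(0, 1, 2, 3, 4),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Half-size dataset for end-to-end tests that retrain repeatedly."""
    config = SyntheticConfig(n_R=40, n_IM=40, n_S=80, p_noise=30, seed=5)
    records, truth = generate_pk_table(config)
    matrix = generate_descriptor_matrix(records, config, truth)
    records = [replace(r, cr_type=None) for r in records]
    return SimpleNamespace(config=config, records=records, truth=truth, matrix=matrix)


@pytest.fixture(scope="session")
def small_system_config():
    return SystemConfig(
        seed=2,
        fup_source="observed",
        boruta_trees=100,
        boruta_max_iter=15,
        rf_trees=100,
    )


@pytest.fixture(scope="session")
def small_system(small_dataset, small_system_config):
    """One trained two-step system on the half-size dataset."""
    bundle = train_system(
        small_dataset.records, small_system_config, matrix=small_dataset.matrix
    )
    return SimpleNamespace(
        bundle=bundle,
        records=small_dataset.records,
        matrix=small_dataset.matrix,
        config=small_system_config,
    )
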