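"""Shared fixtures.

The trained-model fixtures are session-scoped: the desk-scale cohort and
the two trainings (full-data and scenario-3 partial) are the expensive
pieces and several behavioural tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import freept as fp
from freept.training import split_cohort

COHORT_SEED = 100
N_COHORT = 30
DESK_EPOCHS = 150


@pytest.fixture(scope="session")
def cohort():
    """30 synthetic gland pairs under the default study conditions."""
    return [fp.generate_pair(fp.SyntheticPairConfig(seed=COHORT_SEED + i))
            for i in range(N_COHORT)]


@pytest.fixture(scope="session")
def cohort_split(cohort):
    return split_cohort(cohort, test_fraction=0.3, seed=0)


@pytest.fixture(scope="session")
def desk_model(cohort_split):
    """FPT-Chamfer trained at desk scale on the full-data protocol."""
    train_pairs, _ = cohort_split
    cfg = fp.TrainConfig.desk(seed=0, epochs=DESK_EPOCHS)
    model, log = fp.train(cfg, train_pairs)
    return model, log


@pytest.fixture(scope="session")
def scenario3_model(cohort_split):
    """FPT-Chamfer trained with scenario-3 (two skewed slices) target inputs."""
    train_pairs, _ = cohort_split
    cfg = fp.TrainConfig.desk(seed=0, epochs=DESK_EPOCHS, scenario="3")
    model, log = fp.train(cfg, train_pairs)
    return model, log


@pytest.fixture()
def small_pair():
    """One coarse, quick pair for structural tests."""
    return fp.generate_pair(fp.SyntheticPairConfig(seed=7, voxel_spacing=4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
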