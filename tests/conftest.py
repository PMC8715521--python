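"""Shared fixtures: a phantom cohort with a trained sLTP reference model.

The cohort study (five desk-scale phantoms, four for training and one held
out for labeling) is expensive, so it is built once per session and reused
by feature, labeling, visualization and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from sltp.config import RunConfig
from sltp.merge import merge_ltps
from sltp.phantom import truth_class_of_centers
from sltp.pipeline import (build_cohort, child_seed, cohort_training_table,
                           fit_ltps, phantom_study_config)

COHORT_SEED = 1
N_SCANS = 5
TRAIN_IDS = [f"scan{i}" for i in range(4)]


@pytest.fixture(scope="session")
def study_config() -> RunConfig:
    return phantom_study_config(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(study_config):
    return build_cohort(study_config, N_SCANS, COHORT_SEED)


@pytest.fixture(scope="session")
def train_table(cohort):
    return cohort_training_table(cohort["scans"], TRAIN_IDS)


@pytest.fixture(scope="session")
def train_truth(cohort):
    """Planted-class id of every pooled training ROI (0 = normal lung)."""
    return np.concatenate([
        truth_class_of_centers(s.table.subset(s.table.gated).centers,
                               s.bundle["truth_labels"].voxels)
        for s in cohort["scans"][:4]])


@pytest.fixture(scope="session")
def train_result(train_table, study_config):
    return fit_ltps(train_table.ft, train_table.fs, study_config, COHORT_SEED)


@pytest.fixture(scope="session")
def reference_model(train_result, train_table, study_config):
    sltp, graph, part = merge_ltps(train_result.model, train_table.ft,
                                   train_table.fs, train_table.mean_hu,
                                   threshold=study_config.edge_threshold,
                                   seed=child_seed(COHORT_SEED, "merge"))
    return {"sltp": sltp, "graph": graph, "partition": part}


@pytest.fixture(scope="session")
def test_scan(cohort):
    return cohort["scans"][4]


@pytest.fixture(scope="session")
def test_table(test_scan):
    return test_scan.table.subset(test_scan.table.gated)
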