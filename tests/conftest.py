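"""Shared fixtures.

``trained_phantom`` is the expensive shared fixture: a 200-slice phantom
cohort (40 synthetic patients x 5 slices, 64x64), split by patient, and a
reduced-width model taken through batch-norm calibration plus the full
two-stage training protocol. Session-scoped so the training-protocol,
learnability and localization tests all reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from dsanet.data_io import SplitSpec, split_dataset
from dsanet.network import ModelConfig, build_model
from dsanet.synthetic import PhantomSpec, generate_cohort
from dsanet.training import calibrate_batchnorm, records_to_arrays, train_two_stage

COHORT_SEED = 7


@pytest.fixture(scope="session")
def phantom_cohort():
    spec = PhantomSpec(image_size=64)
    records = generate_cohort(40, 5, class_balance=0.5, spec=spec, seed=COHORT_SEED)
    train, val, test = split_dataset(records, SplitSpec(seed=COHORT_SEED))
    return {"records": records, "train": train, "val": val, "test": test, "spec": spec}


@pytest.fixture(scope="session")
def trained_phantom(phantom_cohort):
    config = ModelConfig.smoke(64)
    model = build_model(config, seed=COHORT_SEED)
    xtr, ytr = records_to_arrays(phantom_cohort["train"], config.input_size)
    xval, yval = records_to_arrays(phantom_cohort["val"], config.input_size)
    backbone_before = {k: v.copy() for k, v in model.backbone.get_weights().items()}
    calibrate_batchnorm(model, xtr)
    model, history = train_two_stage(model, (xtr, ytr), (xval, yval), batch_size=16, seed=COHORT_SEED)
    return {
        "model": model,
        "history": history,
        "config": config,
        "backbone_before": backbone_before,
        **phantom_cohort,
    }


@pytest.fixture(scope="session")
def full_model():
    """Canonical 224-px architecture (random weights); built once for the
    parameter-accounting and shape checks."""
    return build_model(ModelConfig(), seed=0)
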