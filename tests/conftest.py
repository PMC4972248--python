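"""Shared fixtures: one default phantom cohort pipeline, reused session-wide."""

import numpy as np
import pytest

import airwaymorph as am

PHANTOM_SEED = 1


@pytest.fixture(scope="session")
def phantom():
    """Default two-group phantom cohort (15 + 15) and its ground truth."""
    cohort, gt = am.generate_phantom_cohort(am.PhantomConfig(seed=PHANTOM_SEED))
    return cohort, gt


@pytest.fixture(scope="session")
def standardizer(phantom):
    cohort, _ = phantom
    return am.train_standardizer([s.intensity for s in cohort],
                                 [s.masks["sk"] for s in cohort])


@pytest.fixture(scope="session")
def phantom_table(phantom, standardizer):
    """Full 30 x 159 feature table extracted from the default phantom cohort."""
    cohort, _ = phantom
    return am.extract_feature_table(cohort, standardizer)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, cheap cohort (2 + 2 subjects on a coarse grid) for I/O tests."""
    cfg = am.PhantomConfig(subjects_per_group=2, grid_shape=(96, 96, 30),
                           voxel_spacing=(1.0, 1.0, 4.0), seed=7)
    cohort, gt = am.generate_phantom_cohort(cfg)
    return cohort, gt
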