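"""Shared fixtures.

The trained-model fixtures are session-scoped because CPU training is the
dominant cost of the suite; the end-to-end tests and the training-strategy
comparison reuse the same cohorts and models.
"""

import pytest

from parotidseg.phantom import PhantomConfig, generate_phantom
from parotidseg.training import TrainConfig, train_patch_model, train_roi_slice_model

COHORT_KW = dict(n_distractors=2)
N_TRAIN = 20
N_EVAL = 10


def _cohort(n, seed0, **kw):
    cases = []
    for i in range(n):
        ph = generate_phantom(PhantomConfig(seed=seed0 + i, **kw))
        cases.append((ph.volume, ph.left_mask))
    return cases


@pytest.fixture(scope="session")
def train_cohort():
    return _cohort(N_TRAIN, 100, **COHORT_KW)


@pytest.fixture(scope="session")
def eval_cohort():
    return _cohort(N_EVAL, 900, **COHORT_KW)


TRAIN3D_CONFIG = TrainConfig(
    dimensionality=3,
    base_channels=4,
    patch_extent=(72, 72, 56),
    batch_size=2,
    fg_fraction=0.5,
    steps=500,
    learning_rate=3e-3,
    seed=7,
)

TRAIN2D_CONFIG = TrainConfig(
    dimensionality=2,
    base_channels=4,
    view="axial",
    batch_size=8,
    steps=250,
    learning_rate=3e-3,
    seed=7,
)


@pytest.fixture(scope="session")
def trained_3d(train_cohort):
    """Reduced-width 3-D U-Net trained with controlled batch composition."""
    model, losses = train_patch_model(train_cohort, TRAIN3D_CONFIG)
    return model, losses


@pytest.fixture(scope="session")
def trained_2d_roi(train_cohort):
    """Reduced-width axial 2-D U-Net trained with the ROI strategy."""
    model, losses = train_roi_slice_model(train_cohort, TRAIN2D_CONFIG)
    return model, losses
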