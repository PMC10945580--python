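import dataclasses

import numpy as np
import pytest

import punctaseg as ps
from punctaseg.synapse import SynapseTrainingConfig

# small grid keeps unit-test trainings fast; contracts under test do not
# depend on the hyperparameter grid
FAST_SYNAPSE_CONFIG = SynapseTrainingConfig(
    grid={"n_estimators": [50], "max_depth": [None]},
    hard_negative_cap=5000,
)


@pytest.fixture(scope="session")
def tiny_spec():
    return ps.preset_spec(
        "small_high_snr", shape=(10, 48, 48),
        neurite_paths=(((5.0, 8.0, 6.0), (4.0, 24.0, 24.0), (5.0, 40.0, 42.0)),),
        n_puncta=8, n_clutter=2, seed=5,
    )


@pytest.fixture(scope="session")
def tiny_sample(tiny_spec):
    return ps.generate_sample(tiny_spec, image_id="tiny")


@pytest.fixture(scope="session")
def tiny_heldout(tiny_spec):
    return ps.generate_sample(dataclasses.replace(tiny_spec, seed=55), image_id="tiny_heldout")


@pytest.fixture(scope="session")
def tiny_model(tiny_sample):
    return ps.train_synapse_model(
        tiny_sample.image, tiny_sample.synapse_truth, seed=0, config=FAST_SYNAPSE_CONFIG
    )


@pytest.fixture
def straight_skeleton():
    """11 collinear nodes spaced 1 voxel apart along x (0..10 µm)."""
    coords = np.array([[0.0, 0.0, float(x)] for x in range(11)])
    return ps.Skeleton(coords=coords, parents=np.r_[-1, np.arange(10)])
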