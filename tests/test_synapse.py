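"""Contracts of the two-layer pixel classifier: patch sampling geometry,
hard-negative growth, neighbour features, mask restriction, label editing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import punctaseg as ps
from punctaseg.synapse import (
    SynapseTrainingConfig,
    compute_patch_side,
    plan_patches,
    train_layer1,
)

from conftest import FAST_SYNAPSE_CONFIG


# ---------------------------------------------------------------------------
# patch geometry


def test_patch_side_mean_area_formula():
    # two in-plane components of areas 9 and 16 → 2·√12.5 ≈ 7.07 → 7
    lab = np.zeros((1, 20, 20), bool)
    lab[0, 1:4, 1:4] = True
    lab[0, 10:14, 10:14] = True
    assert compute_patch_side(ps.LabelVolume(lab)) == 7
    # single component of area 25 → 2·√25 = 10
    lab2 = np.zeros((1, 20, 20), bool)
    lab2[0, 2:7, 2:7] = True
    assert compute_patch_side(ps.LabelVolume(lab2)) == 10


def test_patch_side_floor_and_empty():
    dot = np.zeros((1, 10, 10), bool)
    dot[0, 5, 5] = True  # 2·√1 = 2 → floored to 3
    assert compute_patch_side(ps.LabelVolume(dot)) == 3
    with pytest.raises(ValueError):
        compute_patch_side(ps.LabelVolume(np.zeros((1, 10, 10), bool)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), side=st.integers(3, 9))
def test_every_positive_pixel_lies_in_a_kept_patch(seed, side):
    rng = np.random.default_rng(seed)
    lab = rng.random((3, 17, 23)) > 0.9
    plan = plan_patches(ps.LabelVolume(lab), side)
    covered = np.zeros(lab.shape, bool)
    coords = plan.pixel_coords()
    if len(coords):
        covered[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    assert covered[lab].all()


# ---------------------------------------------------------------------------
# training behaviour


def test_step2_training_set_at_least_step1(tiny_sample):
    result = train_layer1(
        [tiny_sample.image], [tiny_sample.synapse_truth], config=FAST_SYNAPSE_CONFIG
    )
    assert result.step2_size >= result.step1_size


def test_layer2_input_dimension(tiny_model, tiny_sample):
    n_base = tiny_model.bank.vector_length(tiny_sample.image)
    assert tiny_model.layer2.n_features_in_ == n_base + 6
    assert tiny_model.layer1.n_features_in_ == n_base


def test_same_seed_identical_predictions(tiny_sample, tiny_heldout):
    models = [
        ps.train_synapse_model(
            tiny_sample.image, tiny_sample.synapse_truth, seed=3, config=FAST_SYNAPSE_CONFIG
        )
        for _ in range(2)
    ]
    preds = [
        ps.segment_synapses(m, tiny_heldout.image, mask=tiny_heldout.neurite_truth)
        for m in models
    ]
    np.testing.assert_array_equal(preds[0].data, preds[1].data)


def test_training_requires_positive_pixels(tiny_sample):
    empty = ps.LabelVolume(np.zeros(tiny_sample.image.shape, bool))
    with pytest.raises(ValueError):
        train_layer1([tiny_sample.image], [empty], config=FAST_SYNAPSE_CONFIG)


def test_harvest_flag_validation():
    with pytest.raises(ValueError):
        SynapseTrainingConfig(harvest="bogus")
    with pytest.raises(ValueError):
        SynapseTrainingConfig(family="bogus")


# ---------------------------------------------------------------------------
# segmentation contracts


def test_masked_prediction_subset_of_mask(tiny_model, tiny_heldout):
    pred = ps.segment_synapses(tiny_model, tiny_heldout.image, mask=tiny_heldout.neurite_truth)
    assert not (pred.data & ~tiny_heldout.neurite_truth.data).any()


def test_empty_mask_gives_empty_prediction(tiny_model, tiny_heldout):
    empty = ps.LabelVolume(np.zeros(tiny_heldout.image.shape, bool), kind="neurite_mask")
    pred = ps.segment_synapses(tiny_model, tiny_heldout.image, mask=empty)
    assert pred.count() == 0


def test_mask_shape_mismatch_rejected(tiny_model, tiny_heldout):
    bad = ps.LabelVolume(np.zeros((2, 2, 2), bool))
    with pytest.raises(ValueError):
        ps.segment_synapses(tiny_model, tiny_heldout.image, mask=bad)


# ---------------------------------------------------------------------------
# label editing


def test_edit_add_then_remove_is_identity(tiny_sample):
    truth = tiny_sample.synapse_truth
    voxels = np.array([[0, 0, 0], [1, 2, 3], [2, 4, 4]])
    edited = ps.edit_labels(ps.edit_labels(truth, add=voxels), remove=voxels)
    expected = truth.data.copy()
    expected[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = False
    np.testing.assert_array_equal(edited.data, expected)


def test_empty_edit_is_identity(tiny_sample):
    edited = ps.edit_labels(tiny_sample.synapse_truth)
    np.testing.assert_array_equal(edited.data, tiny_sample.synapse_truth.data)
    assert edited.data is not tiny_sample.synapse_truth.data


def test_out_of_bounds_edit_rejected(tiny_sample):
    with pytest.raises(IndexError):
        ps.edit_labels(tiny_sample.synapse_truth, add=[(999, 0, 0)])


def test_corrected_labels_train_without_error(tiny_sample):
    """The predict → correct → retrain loop must close."""
    corrected = ps.edit_labels(
        tiny_sample.synapse_truth, add=[(0, 1, 1), (0, 1, 2)], remove=[(0, 0, 0)]
    )
    model = ps.train_synapse_model(
        tiny_sample.image, corrected, seed=1, config=FAST_SYNAPSE_CONFIG
    )
    assert model.layer1 is not None and model.layer2 is not None


def test_model_save_load_roundtrip(tmp_path, tiny_model, tiny_heldout):
    tiny_model.save(tmp_path / "model.pkl")
    loaded = ps.TwoLayerModel.load(tmp_path / "model.pkl")
    a = ps.segment_synapses(tiny_model, tiny_heldout.image, mask=tiny_heldout.neurite_truth)
    b = ps.segment_synapses(loaded, tiny_heldout.image, mask=tiny_heldout.neurite_truth)
    np.testing.assert_array_equal(a.data, b.data)
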