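"""Chunk geometry, patch filtering, the training loop and mask post-processing."""

import dataclasses

import numpy as np
import pytest

import punctaseg as ps
from punctaseg.neurite import (
    NeuriteTrainingConfig,
    _reflect_indices,
    _remove_somata,
    _tile_positions,
    extract_chunks,
    sample_training_patches,
    split_samples,
    train_neurite_model,
)

TINY_NET = dict(base=4, levels=2, tile=32, patches_per_image=4, batch_size=4)


@pytest.fixture(scope="module")
def tube_samples():
    spec = ps.preset_spec(
        "small_high_snr", shape=(8, 32, 32),
        neurite_paths=(((4.0, 5.0, 4.0), (3.0, 27.0, 28.0)),),
        n_puncta=3, n_clutter=0, seed=11,
    )
    return [(s.image, s.neurite_truth) for s in ps.generate_dataset(spec, 3)]


@pytest.fixture(scope="module")
def tiny_unet(tube_samples):
    cfg = NeuriteTrainingConfig(epochs=15, patience=15, seed=0, **TINY_NET)
    return train_neurite_model(tube_samples[:2], tube_samples[2:], cfg)


def test_one_chunk_per_slice_fullframe():
    img = ps.VolumetricImage({"cytoplasmic": np.random.default_rng(0).random((10, 32, 32))})
    chunks = extract_chunks(img, tile=(32, 32))
    assert len(chunks) == 10
    assert all(c.data.shape == (7, 32, 32) for c in chunks)
    # boundary chunk uses reflected slices: for z=0 the order is 3,2,1,0,1,2,3
    np.testing.assert_array_equal(_reflect_indices(0, 7, 10), [3, 2, 1, 0, 1, 2, 3])
    vol = img.channels["cytoplasmic"]
    np.testing.assert_array_equal(chunks[0].data, vol[[3, 2, 1, 0, 1, 2, 3]])


def test_single_slice_stack_chunks_are_copies_of_it():
    img = ps.VolumetricImage({"cytoplasmic": np.random.default_rng(1).random((1, 16, 16))})
    chunks = extract_chunks(img, tile=(16, 16))
    assert len(chunks) == 1
    for k in range(7):
        np.testing.assert_array_equal(chunks[0].data[k], img.channels["cytoplasmic"][0])


def test_lateral_tiling_arithmetic():
    # frame 300, tile 256, stride 200 → offsets {0, 44} per axis → 4 tiles
    assert _tile_positions(300, 256, 200) == [0, 44]
    img = ps.VolumetricImage({"cytoplasmic": np.zeros((1, 300, 300), np.float32)})
    chunks = extract_chunks(img, tile=256, stride=200)
    assert len(chunks) == 4


def test_patch_sampling_filters_blanks(tube_samples):
    img, truth = tube_samples[0]
    pairs = sample_training_patches(img, truth, n=20, tile=16, blank_threshold=0.0, seed=0)
    assert len(pairs) == 20  # threshold 0 keeps everything
    dark = ps.VolumetricImage({"cytoplasmic": np.zeros((8, 32, 32), np.float32)})
    with pytest.raises(ValueError):
        sample_training_patches(dark, truth, n=5, tile=16, blank_threshold=10.0)
    with pytest.raises(ValueError):
        sample_training_patches(img, ps.LabelVolume(np.zeros((2, 2, 2), bool)), n=5)


def test_training_improves_best_loss(tiny_unet):
    hist = tiny_unet.history
    assert len(hist) >= 2
    best_so_far = np.minimum.accumulate([h["train_loss"] for h in hist])
    assert np.all(np.diff(best_so_far) <= 1e-12)
    assert hist[-1]["train_loss"] < hist[0]["train_loss"]


def test_training_deterministic(tube_samples):
    cfg = NeuriteTrainingConfig(epochs=3, patience=3, seed=7, **TINY_NET)
    m1 = train_neurite_model(tube_samples[:1], config=cfg)
    m2 = train_neurite_model(tube_samples[:1], config=cfg)
    for a, b in zip(m1.net.params, m2.net.params):
        np.testing.assert_array_equal(a, b)


def test_segmentation_shape_and_extreme_threshold(tiny_unet, tube_samples):
    img, truth = tube_samples[2]
    mask = ps.segment_neurites(tiny_unet, img)
    assert mask.shape == img.shape
    empty = ps.segment_neurites(tiny_unet, img, threshold=1.0 + 1e-9)
    assert empty.count() == 0


def test_untrained_model_rejected(tube_samples):
    from punctaseg.neurite import NeuriteModel
    from punctaseg.unet import UNet25D

    model = NeuriteModel(net=UNet25D(base=4, levels=2), config=NeuriteTrainingConfig())
    with pytest.raises(RuntimeError):
        ps.segment_neurites(model, tube_samples[0][0])


def test_model_save_load_identical_outputs(tmp_path, tiny_unet, tube_samples):
    tiny_unet.save(tmp_path / "unet.npz")
    from punctaseg.neurite import NeuriteModel

    loaded = NeuriteModel.load(tmp_path / "unet.npz")
    img = tube_samples[2][0]
    np.testing.assert_array_equal(
        ps.segment_neurites(tiny_unet, img).data, ps.segment_neurites(loaded, img).data
    )


def test_soma_removal_excises_sphere_keeps_tube():
    """A thin tube with a fat sphere: removal drops the sphere's thick
    in-plane regions but keeps the tube."""
    mask = np.zeros((9, 40, 40), bool)
    mask[4, 18:21, :] = True  # tube: 3 voxels thick in-plane
    zz, yy, xx = np.mgrid[0:9, 0:40, 0:40]
    sphere = (zz - 4) ** 2 + (yy - 19) ** 2 + (xx - 30) ** 2 <= 6**2
    cleaned = _remove_somata(mask | sphere, soma_diameter=8.0)
    # sphere centre slice region removed
    assert not cleaned[4, 19, 30]
    # tube far from the sphere survives
    assert cleaned[4, 19, 2]
    assert cleaned[4, 18:21, 0:10].all()


def test_split_samples_ratio():
    train, val, test = split_samples(list(range(16)), ratio=(10, 2, 4), seed=0)
    assert (len(train), len(val), len(test)) == (10, 2, 4)
    assert sorted(train + val + test) == list(range(16))
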