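"""The generator must deliver exactly what its spec promises: deterministic
stacks whose ground truth has the requested structure."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import punctaseg as ps
from punctaseg.synthetic import PlacementError, _polyline_voxels


def n_components26(volume):
    _, n = ndimage.label(volume, structure=np.ones((3, 3, 3), bool))
    return n


def test_truth_component_count_equals_n_puncta(tiny_sample, tiny_spec):
    assert n_components26(tiny_sample.synapse_truth.data) == tiny_spec.n_puncta


@pytest.mark.parametrize("seed", [0, 3, 17, 101])
def test_component_count_across_seeds(seed):
    spec = ps.preset_spec("small_high_snr", shape=(12, 56, 56),
                          neurite_paths=(((6.0, 8.0, 6.0), (5.0, 48.0, 50.0)),),
                          n_puncta=10, seed=seed)
    sample = ps.generate_sample(spec)
    assert n_components26(sample.synapse_truth.data) == 10


def test_same_seed_voxel_identical(tiny_spec):
    a = ps.generate_sample(tiny_spec)
    b = ps.generate_sample(tiny_spec)
    for ch in a.image.channels:
        np.testing.assert_array_equal(a.image.channels[ch], b.image.channels[ch])
    np.testing.assert_array_equal(a.synapse_truth.data, b.synapse_truth.data)
    np.testing.assert_array_equal(a.neurite_truth.data, b.neurite_truth.data)


def test_zero_puncta_gives_empty_truth(tiny_spec):
    spec = dataclasses.replace(tiny_spec, n_puncta=0, n_clutter=0)
    s = ps.generate_sample(spec)
    assert not s.synapse_truth.data.any()
    # synapse channel is then just background + noise
    resid = s.image.synapse - spec.background_level
    assert abs(resid.mean()) < 3 * spec.noise_sd


def test_measured_snr_matches_nominal():
    """(mean punctum peak − background)/noise_sd ≈ nominal SNR over seeds."""
    spec = ps.preset_spec("small_high_snr", shape=(10, 48, 48),
                          neurite_paths=(((5.0, 8.0, 6.0), (4.0, 40.0, 42.0)),),
                          n_puncta=6, n_clutter=0)
    peaks = []
    for seed in range(20):
        s = ps.generate_sample(dataclasses.replace(spec, seed=seed))
        peaks.extend(s.image.synapse[c] for c, _ in s.puncta_truth)
    measured = (np.mean(peaks) - spec.background_level) / spec.noise_sd
    assert abs(measured - spec.nominal_snr) <= 0.10 * spec.nominal_snr


def test_truth_voxels_near_skeleton(tiny_sample, tiny_spec):
    path = _polyline_voxels(tiny_spec.neurite_paths, tiny_spec.shape)
    on_path = np.zeros(tiny_spec.shape, bool)
    on_path[tuple(path.T)] = True
    dist = ndimage.distance_transform_edt(~on_path)
    reach = tiny_spec.neurite_radius + tiny_spec.puncta_radius_range[1]
    assert dist[tiny_sample.synapse_truth.data].max() <= reach


def test_puncta_centers_on_neurite(tiny_sample):
    dilated = ndimage.binary_dilation(tiny_sample.neurite_truth.data)
    for center, _ in tiny_sample.puncta_truth:
        assert dilated[center]


def test_placement_error_reports_achieved_count():
    spec = ps.preset_spec("small_high_snr", shape=(6, 16, 16),
                          neurite_paths=(((3.0, 8.0, 2.0), (3.0, 8.0, 13.0)),),
                          n_puncta=60, n_clutter=0)
    with pytest.raises(PlacementError) as err:
        ps.generate_sample(spec)
    assert 0 <= err.value.achieved < 60


def test_dataset_determinism_and_length(tiny_spec):
    spec = dataclasses.replace(tiny_spec, n_puncta=4)
    assert len(ps.generate_dataset(spec, 1)) == 1
    a = ps.generate_dataset(spec, 3)
    b = ps.generate_dataset(spec, 3)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.image.synapse, sb.image.synapse)
    # samples are not copies of one another
    assert not np.array_equal(a[0].image.synapse, a[1].image.synapse)
    with pytest.raises(ValueError):
        ps.generate_dataset(spec, 0)


def test_spec_validation():
    with pytest.raises(ValueError):
        ps.SyntheticSpec(n_puncta=-1)
    with pytest.raises(ValueError):
        ps.SyntheticSpec(puncta_radius_range=(3.0, 1.0))
    with pytest.raises(ValueError):
        ps.SyntheticSpec(neurite_paths=(((0.0, 0.0, 500.0), (1.0, 1.0, 1.0)),))
    with pytest.raises(KeyError):
        ps.preset_spec("nonexistent")


def test_save_sample_writes_all_artifacts(tmp_path, tiny_sample):
    ps.save_sample(tiny_sample, tmp_path / "s0")
    for name in ["synapse.tif", "cytoplasmic.tif", "neurite_truth.tif",
                 "synapse_truth.tif", "skeleton.swc", "puncta_truth.csv", "spec.json"]:
        assert (tmp_path / "s0" / name).exists()
    truth = ps.read_label(tmp_path / "s0" / "synapse_truth.tif")
    np.testing.assert_array_equal(truth.data, tiny_sample.synapse_truth.data)
    skel = ps.load_skeleton(tmp_path / "s0" / "skeleton.swc")
    assert skel.n_nodes == tiny_sample.skeleton_truth.n_nodes
    # the stored config round-trips to an identical spec (hence dataset)
    assert ps.load_spec(tmp_path / "s0" / "spec.json") == tiny_sample.spec
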