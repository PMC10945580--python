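"""Puncta extraction against a flood-fill oracle, skeleton geometry and
distribution normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import punctaseg as ps
from punctaseg.quantify import (
    DIFFUSE_SIZE_THRESHOLD,
    extract_puncta,
    map_puncta_to_skeleton,
    population_density,
    summarize_image,
)

# ---------------------------------------------------------------------------
# independent flood-fill oracle

_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def floodfill_components(volume, connectivity):
    """Brute-force BFS component labelling — the oracle."""
    seen = np.zeros(volume.shape, bool)
    comps = []
    for start in map(tuple, np.argwhere(volume)):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in _OFFSETS[connectivity]:
                n = tuple(np.add(v, off))
                if all(0 <= n[i] < volume.shape[i] for i in range(3)):
                    if volume[n] and not seen[n]:
                        seen[n] = True
                        stack.append(n)
        comps.append(frozenset(comp))
    return set(comps)


def _image_like(volume, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(0)
    return ps.VolumetricImage(
        {"synapse": rng.random(volume.shape).astype(np.float32) + 1.0}, spacing=spacing
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 100_000),
    connectivity=st.sampled_from([6, 18, 26]),
    density=st.floats(0.05, 0.6),
)
def test_components_match_floodfill_oracle(seed, connectivity, density):
    rng = np.random.default_rng(seed)
    vol = rng.random((6, 7, 8)) < density
    puncta = extract_puncta(ps.LabelVolume(vol), _image_like(vol), connectivity=connectivity)
    got = {frozenset(map(tuple, p.voxels)) for p in puncta.puncta}
    assert got == floodfill_components(vol, connectivity)


def test_corner_touching_voxels_connectivity_dependent():
    vol = np.zeros((3, 3, 3), bool)
    vol[0, 0, 0] = True
    vol[1, 1, 1] = True
    img = _image_like(vol)
    assert len(extract_puncta(ps.LabelVolume(vol), img, connectivity=26)) == 1
    assert len(extract_puncta(ps.LabelVolume(vol), img, connectivity=6)) == 2


def test_volume_conservation_and_disjointness(tiny_sample):
    pred = tiny_sample.synapse_truth
    puncta = extract_puncta(pred, tiny_sample.image)
    assert puncta.total_voxels == pred.count()
    all_vox = np.vstack([p.voxels for p in puncta.puncta])
    assert len(np.unique(all_vox, axis=0)) == len(all_vox)
    voxel_volume = tiny_sample.image.voxel_volume
    assert sum(p.volume_um3 for p in puncta.puncta) == pytest.approx(
        pred.count() * voxel_volume
    )


def test_intensity_statistics_from_synapse_channel():
    vol = np.zeros((2, 3, 3), bool)
    vol[0, 0, :3] = True
    data = np.zeros((2, 3, 3), np.float32)
    data[0, 0] = [2.0, 4.0, 6.0]
    img = ps.VolumetricImage({"synapse": data})
    p = extract_puncta(ps.LabelVolume(vol), img).puncta[0]
    assert (p.mean_intensity, p.max_intensity, p.total_intensity) == (4.0, 6.0, 12.0)


def test_min_size_filter():
    vol = np.zeros((3, 6, 6), bool)
    vol[1, 1, 1] = True
    vol[1, 4, 3:6] = True
    img = _image_like(vol)
    assert len(extract_puncta(ps.LabelVolume(vol), img, min_size=2)) == 1


# ---------------------------------------------------------------------------
# skeletons


def test_collinear_swc_arc_length(tmp_path):
    rows = [(i + 1, 3 if i else 1, float(i), 0.0, 0.0, 1.0, i if i else -1)
            for i in range(11)]
    ps.io.write_swc(rows, tmp_path / "line.swc")
    sk = ps.load_skeleton(tmp_path / "line.swc")
    assert sk.total_length == pytest.approx(10.0)


def test_single_node_skeleton(tmp_path):
    ps.io.write_swc([(1, 1, 0.0, 0.0, 0.0, 1.0, -1)], tmp_path / "dot.swc")
    sk = ps.load_skeleton(tmp_path / "dot.swc")
    assert sk.total_length == 0.0
    vol = np.zeros((2, 2, 2), bool)
    vol[0, 0, 0] = True
    puncta = extract_puncta(ps.LabelVolume(vol), _image_like(vol))
    mapped = map_puncta_to_skeleton(puncta, sk)
    assert mapped.puncta[0].position_norm == pytest.approx(0.0)


def test_multiple_roots_rejected(tmp_path):
    rows = [(1, 1, 0, 0, 0, 1.0, -1), (2, 3, 1, 0, 0, 1.0, -1)]
    ps.io.write_swc(rows, tmp_path / "two.swc")
    with pytest.raises(ValueError):
        ps.load_skeleton(tmp_path / "two.swc")


def test_cycle_rejected():
    with pytest.raises(ValueError):
        ps.Skeleton(coords=np.zeros((3, 3)), parents=np.array([2, 0, 1]))


def test_anisotropic_spacing_in_arc_length():
    coords = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], float)
    sk = ps.Skeleton(coords=coords, parents=np.array([-1, 0, 1]), spacing=(1.0, 1.0, 0.25))
    assert sk.total_length == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# mapping


def _puncta_at(voxel_sets, shape=(3, 5, 12)):
    vol = np.zeros(shape, bool)
    for vs in voxel_sets:
        for v in vs:
            vol[v] = True
    return extract_puncta(ps.LabelVolume(vol), _image_like(vol))


def test_lateral_centroid_maps_to_nearest_node(straight_skeleton):
    puncta = _puncta_at([[(0, 1, 3)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    assert mapped.puncta[0].skeleton_node_index == 3
    assert mapped.puncta[0].position_norm == pytest.approx(0.3)


def test_endpoint_puncta_map_to_zero_and_one(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 0)], [(2, 0, 10)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    positions = sorted(p.position_norm for p in mapped.puncta)
    assert positions == [0.0, 1.0]


def test_tie_broken_toward_soma(straight_skeleton):
    # centroid exactly between nodes 4 and 5
    puncta = _puncta_at([[(0, 1, 4), (0, 1, 5)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    assert mapped.puncta[0].skeleton_node_index == 4


def test_per_voxel_mode_contributes_both_positions(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 4), (0, 0, 5)]])
    mapped = map_puncta_to_skeleton(
        puncta, straight_skeleton, mode="per_voxel", size_threshold=2
    )
    entries = mapped.puncta[0].position_entries
    assert sorted(entries[:, 0]) == [pytest.approx(0.4), pytest.approx(0.5)]
    assert entries[:, 1].tolist() == [1.0, 1.0]


def test_default_size_threshold_is_radius10_sphere():
    assert DIFFUSE_SIZE_THRESHOLD == sum(
        1
        for z in range(-10, 11)
        for y in range(-10, 11)
        for x in range(-10, 11)
        if z * z + y * y + x * x <= 100
    )


def test_synapse_domain_rescaling_hits_exact_endpoints(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 2)], [(0, 0, 5)], [(0, 0, 8)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton, normalization="synapse_domain")
    positions = sorted(p.position_norm for p in mapped.puncta)
    assert positions[0] == 0.0
    assert positions[-1] == 1.0
    assert positions[1] == pytest.approx(0.5)


def test_invalid_mapping_mode_rejected(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 2)]])
    with pytest.raises(ValueError):
        map_puncta_to_skeleton(puncta, straight_skeleton, mode="bogus")


# ---------------------------------------------------------------------------
# distributions and summaries


def test_point_mass_density(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 5)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    prof = population_density([mapped], n_bins=10)
    assert prof.integral() == pytest.approx(1.0, abs=1e-9)
    assert prof.density[5] == pytest.approx(10.0)
    assert np.count_nonzero(prof.density) == 1


def test_identical_worms_do_not_change_density(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 2)], [(0, 0, 7)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    one = population_density([mapped], n_bins=10)
    two = population_density([mapped, mapped], n_bins=10)
    np.testing.assert_allclose(one.density, two.density)


def test_density_integral_always_one(tiny_sample):
    puncta = extract_puncta(tiny_sample.synapse_truth, tiny_sample.image)
    mapped = map_puncta_to_skeleton(puncta, tiny_sample.skeleton_truth)
    for bins in (5, 17, 50):
        assert population_density([mapped], n_bins=bins).integral() == pytest.approx(
            1.0, abs=1e-9
        )


def test_mixed_normalization_modes_rejected(straight_skeleton):
    puncta = _puncta_at([[(0, 0, 2)]])
    a = map_puncta_to_skeleton(puncta, straight_skeleton, normalization="entire_neurite")
    b = map_puncta_to_skeleton(puncta, straight_skeleton, normalization="synapse_domain")
    with pytest.raises(ValueError):
        population_density([a, b])


def test_summary_domain_and_densities(straight_skeleton):
    # 5 disconnected puncta whose extreme nodes sit at 2 µm and 7 µm → domain 5 µm
    puncta = _puncta_at([[(0, 0, 2)], [(0, 2, 3)], [(0, 4, 4)], [(0, 2, 6)], [(0, 0, 7)]])
    mapped = map_puncta_to_skeleton(puncta, straight_skeleton)
    s = summarize_image(mapped)
    assert s.domain_length == pytest.approx(5.0)
    assert s.count_density == pytest.approx(1.0)
    assert s.volume_density == pytest.approx(1.0)  # 5 µm³ over 5 µm


def test_single_punctum_degenerate_domain(straight_skeleton):
    mapped = map_puncta_to_skeleton(_puncta_at([[(0, 0, 4)]]), straight_skeleton)
    s = summarize_image(mapped)
    assert s.domain_length == 0.0
    assert s.count_density is None and s.volume_density is None


def test_empty_set_summary_zeros():
    empty = ps.PunctaSet(puncta=[], image_id="x")
    s = summarize_image(empty)
    assert s.puncta_count == 0
    assert s.total_volume == 0.0
    assert s.count_density == 0.0


def test_truth_positions_recovered_from_generator(tiny_sample, tiny_spec):
    """Puncta placed on the neurite are recovered near their true arc position."""
    skel = tiny_sample.skeleton_truth
    puncta = extract_puncta(tiny_sample.synapse_truth, tiny_sample.image)
    mapped = map_puncta_to_skeleton(puncta, skel)
    true_positions = {
        tuple(c): skel.arc_length[int(skel.nearest_node(np.asarray(c, float))[0])]
        / skel.total_length
        for c, _ in tiny_sample.puncta_truth
    }
    errors = []
    for p in mapped.puncta:
        nearest_truth = min(
            true_positions,
            key=lambda c: np.linalg.norm(np.asarray(c) - np.asarray(p.centroid)),
        )
        errors.append(abs(p.position_norm - true_positions[nearest_truth]))
    assert np.mean(errors) < 2.0 / skel.total_length
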