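"""Morphometric core: EDT, skeleton graph, lengths, thickness, topology."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from spiculometry import morphometry, phantoms
from spiculometry.morphometry import (
    build_skeleton_graph,
    compute_surface_area,
    compute_volume,
    count_tips_junctions,
    euclidean_distance_transform,
    mean_thickness,
    measure_labels,
    measure_spicule,
    prune_spurs,
    skeletonize_3d,
    total_length,
)
from spiculometry.volume_io import VoxelVolume

from conftest import measured_junctions_um


def edt_bruteforce(mask, spacing):
    """O(n²) oracle: nearest background voxel centre, volume padded by 1."""
    pm = np.pad(np.asarray(mask) != 0, 1)
    sp = np.asarray(spacing, dtype=float)
    bg = np.argwhere(~pm) * sp
    fg = np.argwhere(pm)
    out = np.zeros(pm.shape)
    if len(fg):
        d, _ = cKDTree(bg).query(fg * sp)
        out[tuple(fg.T)] = d
    return out[1:-1, 1:-1, 1:-1]


class TestEDT:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        d = euclidean_distance_transform(m, (1, 1, 1))
        assert d[1, 1, 1] == 1.0
        assert d.sum() == 1.0

    def test_block_center_with_implicit_padding(self):
        m = np.ones((5, 5, 5), bool)
        d = euclidean_distance_transform(m, (1, 1, 1))
        assert d[2, 2, 2] == 3.0  # three voxels to the padded background

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (2.0, 1.0, 0.7)])
    def test_matches_bruteforce_oracle(self, spacing):
        rng = np.random.default_rng(12345)
        for _ in range(40):
            m = rng.random((12, 12, 12)) < rng.uniform(0.2, 0.8)
            got = euclidean_distance_transform(m, spacing)
            want = edt_bruteforce(m, spacing)
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestSkeletonize:
    def test_single_voxel_is_its_own_skeleton(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert np.array_equal(skeletonize_3d(m), m)

    def test_empty_input_gives_empty_skeleton(self):
        assert skeletonize_3d(np.zeros((4, 4, 4), bool)).sum() == 0

    def test_capsule_skeleton_is_single_path_with_bounded_extent(self):
        prim = phantoms.RodPrimitive((0, 0, 0), (0, 0, 50.0), 3.0)
        vol, _ = phantoms.make_rod_phantom(phantoms.PhantomSpec((prim,)))
        sk = skeletonize_3d(vol.values)
        g = build_skeleton_graph(sk, vol.spacing)
        assert len(g.branches) == 1
        ends = [n for n in g.nodes.values() if n.kind == "endpoint"]
        assert len(ends) == 2
        extent = np.linalg.norm(
            np.subtract(ends[0].coordinate, ends[1].coordinate).astype(float)
        )
        assert 44.0 <= extent <= 50.0  # thinning shortens each end by <= r

    def test_skeleton_subset_of_foreground_and_component_preserving(self):
        rng = np.random.default_rng(7)
        blobs = np.zeros((30, 30, 30), bool)
        for c in rng.integers(5, 25, size=(4, 3)):
            blobs[tuple(slice(x - 3, x + 4) for x in c)] = True
        sk = skeletonize_3d(blobs)
        assert not np.any(sk & ~blobs)
        s26 = ndimage.generate_binary_structure(3, 3)
        assert ndimage.label(sk, s26)[1] == ndimage.label(blobs, s26)[1]


def line_mask(n=11):
    m = np.zeros((3, 3, n + 2), bool)
    m[1, 1, 1 : n + 1] = True
    return m


class TestSkeletonGraph:
    def test_collinear_voxels(self):
        g = build_skeleton_graph(line_mask(11), (1, 1, 1))
        assert count_tips_junctions(g) == (2, 0)
        assert len(g.branches) == 1
        assert len(g.branches[0].path) == 11

    def test_y_of_three_arms(self):
        m = np.zeros((3, 25, 25), bool)
        m[1, 12, 2:13] = True  # horizontal arm into (12,12)
        m[1, 2:12, 12] = True  # vertical arm
        m[1, range(13, 23), range(13, 23)] = True  # diagonal arm
        g = build_skeleton_graph(m, (1, 1, 1))
        tips, juncs = count_tips_junctions(g)
        assert (tips, juncs) == (3, 1)
        assert len(g.branches) == 3

    def test_adjacent_degree3_voxels_merge_to_one_junction(self):
        # T where the crossbar voxel and its vertical neighbour both have deg >= 3
        m = np.zeros((3, 9, 13), bool)
        m[1, 1, 1:12] = True
        m[1, 2:8, 6] = True
        g = build_skeleton_graph(m, (1, 1, 1))
        tips, juncs = count_tips_junctions(g)
        assert juncs == 1
        assert tips == 3
        junction = [n for n in g.nodes.values() if n.kind == "junction"][0]
        assert len(junction.voxels) >= 2  # the adjacent deg-3 voxels merged

    def test_solid_block_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        with pytest.raises(ValueError, match="not a thinned mask"):
            build_skeleton_graph(m, (1, 1, 1))

    def test_isolated_cycle_gets_anchor_and_closed_branch(self):
        # diamond ring: every voxel has exactly two diagonal neighbours
        m = np.zeros((3, 11, 11), bool)
        for y in range(11):
            for x in range(11):
                if abs(y - 5) + abs(x - 5) == 4:
                    m[1, y, x] = True
        g = build_skeleton_graph(m, (1, 1, 1))
        assert count_tips_junctions(g) == (0, 0)
        assert len(g.branches) == 1
        br = g.branches[0]
        assert br.node_a == br.node_b
        assert g.nodes[br.node_a].kind == "anchor"

    def test_euler_relation_on_acyclic_phantoms(self, triradiate_phantom):
        vol, _ = triradiate_phantom
        sk = skeletonize_3d(vol.values)
        g = build_skeleton_graph(sk, vol.spacing)
        # connected acyclic component: n_branches = n_nodes - 1
        assert len(g.branches) == len(g.nodes) - 1


class TestPruneSpurs:
    def test_single_branch_unchanged(self):
        g = build_skeleton_graph(line_mask(100), (1, 1, 1))
        gp = prune_spurs(g, min_length_um=5.0)
        assert total_length(gp) == total_length(g)

    def test_short_arm_removed_junction_dissolves(self):
        m = np.zeros((3, 60, 110), bool)
        m[1, 5, 5:105] = True  # 100-voxel bar
        m[1, 6:8, 55] = True  # 2-voxel spur
        g = build_skeleton_graph(m, (1, 1, 1))
        assert count_tips_junctions(g) == (3, 1)
        gp = prune_spurs(g, min_length_um=5.0)
        assert count_tips_junctions(gp) == (2, 0)

    def test_idempotent(self):
        m = np.zeros((3, 60, 110), bool)
        m[1, 5, 5:105] = True
        m[1, 6:8, 55] = True
        m[1, 6:9, 80] = True
        g = prune_spurs(build_skeleton_graph(m, (1, 1, 1)), min_length_um=5.0)
        g2 = prune_spurs(g, min_length_um=5.0)
        assert g.voxels == g2.voxels

    def test_never_removes_last_branch(self):
        g = build_skeleton_graph(line_mask(4), (1, 1, 1))
        gp = prune_spurs(g, min_length_um=100.0)
        assert len(gp.branches) == 1


class TestTotalLength:
    def test_collinear_both_modes(self):
        g = build_skeleton_graph(line_mask(11), (1, 1, 1))
        assert total_length(g, "path") == pytest.approx(10.0)
        assert total_length(g, "chord") == pytest.approx(10.0)

    def test_diagonal_steps(self):
        m = np.zeros((8, 8, 8), bool)
        for i in range(6):
            m[i + 1, i + 1, i + 1] = True
        g = build_skeleton_graph(m, (1, 1, 1))
        assert total_length(g, "path") == pytest.approx(5 * np.sqrt(3))
        assert total_length(g, "chord") == pytest.approx(5 * np.sqrt(3))

    def test_chord_undermeasures_bent_path(self):
        m = np.zeros((3, 12, 12), bool)
        m[1, 1, 1:11] = True
        m[1, 2:11, 10] = True
        g = build_skeleton_graph(m, (1, 1, 1))
        assert total_length(g, "chord") < total_length(g, "path")

    def test_anisotropic_spacing_scales_steps(self):
        g = build_skeleton_graph(line_mask(11), (1, 1, 2.0))
        assert total_length(g, "path") == pytest.approx(20.0)

    def test_triradiate_close_to_truth(self, triradiate_phantom):
        vol, truth = triradiate_phantom
        rec, _ = measure_spicule(vol.values, vol.spacing)
        assert rec["total_length_um"] == pytest.approx(
            truth.total_centerline_length_um, rel=0.05
        )


class TestMeanThickness:
    def test_one_voxel_wide_line_radius_one(self):
        m = line_mask(20)
        sk = m.copy()
        assert mean_thickness(m, sk, (1, 1, 1), mode="radius") == pytest.approx(1.0)

    def test_capsule_radius_recovered(self, capsule_measured):
        record, details, truth = capsule_measured
        r = record["mean_thickness_um"] / 2
        assert r == pytest.approx(truth.radius_um, rel=0.10)

    def test_diameter_is_twice_radius(self, capsule_phantom):
        vol, _ = capsule_phantom
        sk = skeletonize_3d(vol.values)
        r = mean_thickness(vol.values, sk, vol.spacing, mode="radius")
        d = mean_thickness(vol.values, sk, vol.spacing, mode="diameter")
        assert d == 2 * r

    def test_erosion_strictly_decreases_thickness(self, capsule_phantom):
        vol, _ = capsule_phantom
        m = vol.values.astype(bool)
        er = ndimage.binary_erosion(m)
        t1 = mean_thickness(m, skeletonize_3d(m), vol.spacing)
        t2 = mean_thickness(er, skeletonize_3d(er), vol.spacing)
        assert t2 < t1

    def test_empty_skeleton_rejected(self):
        m = line_mask(5)
        with pytest.raises(ValueError, match="empty skeleton"):
            mean_thickness(m, np.zeros_like(m), (1, 1, 1))


class TestVolumeArea:
    def test_cube_volume_and_spacing_scaling(self):
        cube = np.ones((10, 10, 10), np.int32)
        v1 = VoxelVolume(cube, (1, 1, 1), kind="labels")
        assert compute_volume(v1, 1) == 1000.0
        v2 = VoxelVolume(cube, (0.65, 0.65, 0.65), kind="labels")
        assert compute_volume(v2, 1) == pytest.approx(274.625)

    def test_unknown_label_raises(self):
        v = VoxelVolume(np.ones((2, 2, 2), np.int32), (1, 1, 1), kind="labels")
        with pytest.raises(ValueError, match="unknown label"):
            compute_volume(v, 5)

    def test_cube_voxel_face_area_exact(self):
        v = VoxelVolume(np.ones((10, 10, 10), np.int32), (1, 1, 1), kind="labels")
        assert compute_surface_area(v, 1, method="voxel_face") == 600.0

    def test_ball_mesh_area_within_5pct(self):
        g = np.arange(-14, 15)
        Z, Y, X = np.meshgrid(g, g, g, indexing="ij")
        ball = (Z**2 + Y**2 + X**2 <= 100).astype(np.int32)
        v = VoxelVolume(ball, (1, 1, 1), kind="labels")
        area = compute_surface_area(v, 1, method="mesh")
        assert area == pytest.approx(4 * np.pi * 100, rel=0.05)

    def test_area_invariant_under_grid_rotation(self, capsule_phantom):
        vol, _ = capsule_phantom
        v = VoxelVolume(vol.values.astype(np.int32), (1, 1, 1), kind="labels")
        r = VoxelVolume(
            np.rot90(vol.values, 1, (0, 2)).astype(np.int32), (1, 1, 1), kind="labels"
        )
        a0 = compute_surface_area(v, 1, "mesh")
        a1 = compute_surface_area(r, 1, "mesh")
        assert a1 == pytest.approx(a0, rel=1e-6)


class TestMeasureSpicule:
    def test_capsule_end_to_end_against_truth(self, capsule_measured):
        record, _, truth = capsule_measured
        assert record["volume_um3"] == pytest.approx(truth.analytic_volume_um3, rel=0.05)
        assert record["total_length_um"] == pytest.approx(
            truth.total_centerline_length_um, rel=0.05
        )
        assert record["mean_thickness_um"] / 2 == pytest.approx(truth.radius_um, rel=0.10)
        assert record["n_tips"] == truth.expected_tips
        assert record["n_junctions"] == truth.expected_junctions

    def test_tip_split_junction_near_rod_end(self, tip_split_phantom):
        vol, truth = tip_split_phantom
        rec, det = measure_spicule(vol.values, vol.spacing, origin=vol.origin)
        assert (rec["n_tips"], rec["n_junctions"]) == (3, 1)
        d = min(
            np.linalg.norm(j - np.asarray(truth.junction_points_um[0]))
            for j in measured_junctions_um(det)
        )
        assert d <= 10.0

    def test_back_branch_junction_near_midpoint(self, back_branch_phantom):
        vol, truth = back_branch_phantom
        rec, det = measure_spicule(vol.values, vol.spacing, origin=vol.origin)
        assert (rec["n_tips"], rec["n_junctions"]) == (3, 1)
        d = min(
            np.linalg.norm(j - np.asarray(truth.junction_points_um[0]))
            for j in measured_junctions_um(det)
        )
        assert d <= 10.0

    def test_measurements_invariant_under_axis_rotation(self, capsule_phantom):
        vol, _ = capsule_phantom
        rec0, _ = measure_spicule(vol.values, (1, 1, 1))
        for k, axes in [(1, (0, 2)), (1, (1, 2)), (3, (0, 1))]:
            rec, _ = measure_spicule(np.rot90(vol.values, k, axes), (1, 1, 1))
            assert rec["volume_um3"] == rec0["volume_um3"]
            assert (rec["n_tips"], rec["n_junctions"]) == (
                rec0["n_tips"],
                rec0["n_junctions"],
            )
            # thinning is not exactly rotation-equivariant; ends may move
            # by a voxel or two depending on the scan direction
            assert rec["total_length_um"] == pytest.approx(
                rec0["total_length_um"], rel=0.03
            )

    def test_length_scales_linearly_volume_cubically_with_spacing(self):
        prim = phantoms.RodPrimitive((0, 0, 0), (0, 0, 60.0), 4.0)
        vol, _ = phantoms.make_rod_phantom(phantoms.PhantomSpec((prim,)))
        r1, _ = measure_spicule(vol.values, (1, 1, 1))
        r2, _ = measure_spicule(vol.values, (2, 2, 2))
        assert r2["total_length_um"] == pytest.approx(2 * r1["total_length_um"])
        assert r2["volume_um3"] == pytest.approx(8 * r1["volume_um3"])

    def test_anisotropic_input_measures_in_physical_units(self):
        # same rod sampled at half z-resolution: skeleton runs along z
        prim = phantoms.RodPrimitive((0, 0, 0), (60.0, 0, 0), 4.0)
        iso, _ = phantoms.make_rod_phantom(
            phantoms.PhantomSpec((prim,), spacing=(1, 1, 1))
        )
        aniso, _ = phantoms.make_rod_phantom(
            phantoms.PhantomSpec((prim,), spacing=(2.0, 1.0, 1.0))
        )
        r_iso, _ = measure_spicule(iso.values, (1, 1, 1))
        r_aniso, _ = measure_spicule(aniso.values, (2.0, 1.0, 1.0))
        # coarse z-sampling (spacing = r/2) blurs the rounded caps, so the
        # skeleton can run ~a radius further into each cap than at 1 µm
        assert r_aniso["total_length_um"] == pytest.approx(60.0, rel=0.10)
        assert r_iso["total_length_um"] == pytest.approx(60.0, rel=0.05)
        assert r_aniso["mean_thickness_um"] == pytest.approx(
            r_iso["mean_thickness_um"], rel=0.15
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_spicule(np.zeros((4, 4, 4)), (1, 1, 1))


class TestMeasureLabels:
    def test_cohort_of_phantoms_one_record_each(self):
        # place three separated rods in one volume
        prim = phantoms.RodPrimitive((0, 0, 0), (0, 0, 100.0), 4.0)
        single, _ = phantoms.make_rod_phantom(phantoms.PhantomSpec((prim,)))
        sz, sy, sx = single.values.shape
        arr = np.zeros((3 * sz + 20, sy + 20, sx + 10), np.uint8)
        for i in range(3):
            z0 = 2 + i * (sz + 5)
            arr[z0 : z0 + sz, 10 : 10 + sy, 5 : 5 + sx] |= single.values
        vol = VoxelVolume(arr, (1, 1, 1), kind="binary")
        recs = measure_labels(vol, condition="control", timepoint_hpf=48.0)
        assert len(recs) == 3
        assert recs["spicule_id"].is_unique
        np.testing.assert_allclose(recs["total_length_um"], 98.0, rtol=0.03)

    def test_records_stable_across_reruns(self, capsule_phantom):
        vol, _ = capsule_phantom
        v = VoxelVolume(vol.values, vol.spacing, kind="binary")
        a = measure_labels(v)
        b = measure_labels(v)
        assert a.equals(b)
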