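"""Voxel-to-tet meshing, surface labeling, anatomical frame, load cases."""

import numpy as np
import pytest

import vertefem as vf
from vertefem import io as vio
from vertefem.calibration import CalibrationLine, hu_to_density
from vertefem.meshing import TetMesh, face_counts


class TestSubdivision:
    def test_six_tets_per_voxel_and_exact_volume(self, bar):
        mesh, vol = bar["mesh"], bar["volume"]
        n_vox = int(vol.mask.sum())
        assert mesh.n_elements == 6 * n_vox
        assert mesh.element_volumes().sum() == pytest.approx(n_vox * 1.0, rel=1e-12)

    def test_single_voxel_mesh(self):
        vol = vf.make_bar_phantom(1.0, 1.0, 500.0, 1.0)
        rho = hu_to_density(vol, CalibrationLine())
        mesh = vf.voxels_to_tets(vol, rho)
        assert mesh.n_nodes == 8 and mesh.n_elements == 6
        np.testing.assert_allclose(mesh.element_volumes(), 1.0 / 6.0, rtol=1e-12)

    def test_conformity_interior_faces_shared_by_two(self, bar):
        counts = face_counts(bar["mesh"].tets)
        assert set(np.unique(counts)) <= {1, 2}

    def test_positive_orientation_and_no_orphans(self, vertebra):
        vertebra["mesh"].validate()

    def test_element_density_inherited_six_fold(self, vertebra):
        dens = vertebra["mesh"].element_density
        assert len(dens) == vertebra["mesh"].n_elements
        # six consecutive elements per voxel share the voxel density
        assert np.all(dens.reshape(-1, 6) == dens.reshape(-1, 6)[:, :1])

    def test_refinement_conserves_volume(self):
        spec = vf.PhantomSpec(height=8.0, semi_axis_ap=6.0, semi_axis_ml=5.0, voxel=2.0, seed=0)
        fine_spec = vf.PhantomSpec(height=8.0, semi_axis_ap=6.0, semi_axis_ml=5.0, voxel=1.0, seed=0)
        vols = []
        for s in (spec, fine_spec):
            v = vf.make_vertebra_phantom(s)
            m = vf.voxels_to_tets(v, hu_to_density(v, CalibrationLine()))
            vols.append(m.element_volumes().sum())
        # surface voxel layer bounds the volume change under halving
        layer = 6.0 * 2 * np.pi * 5.5 * 2.0  # height x perimeter-ish x coarse voxel
        assert abs(vols[1] - vols[0]) < layer


class TestSurfaces:
    def test_bar_cranial_set_is_top_grid(self, bar):
        mesh = bar["mesh"]
        assert len(mesh.node_sets["cranial"]) == 25  # (4+1)^2
        assert np.all(mesh.nodes[mesh.node_sets["cranial"]][:, 2] == 10.0)
        assert np.all(mesh.nodes[mesh.node_sets["caudal"]][:, 2] == 0.0)

    def test_sets_disjoint(self, vertebra):
        s = vertebra["mesh"].node_sets
        assert len(np.intersect1d(s["cranial"], s["caudal"])) == 0

    def test_waisted_phantom_lateral_nodes_unlabelled(self, vertebra):
        mesh = vertebra["mesh"]
        z = mesh.nodes[:, 2]
        lo, hi = z.min(), z.max()
        band = 0.10 * (hi - lo)
        labelled = np.union1d(mesh.node_sets["cranial"], mesh.node_sets["caudal"])
        mid = np.nonzero((z > lo + band) & (z < hi - band))[0]
        assert len(np.intersect1d(labelled, mid)) == 0


class TestFrame:
    def test_bar_frame_axis_aligned(self, bar):
        frame = vf.build_frame(bar["mesh"])
        np.testing.assert_allclose(np.abs(frame.transverse_normal), [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(frame.center_of_mass, [0, 0, 5.0], atol=1e-9)
        assert frame.body_width == pytest.approx(4.0)
        assert frame.axial_extent == pytest.approx(10.0)

    def test_com_invariant_under_uniform_density_scaling(self, bar):
        mesh = bar["mesh"]
        frame1 = vf.build_frame(mesh)
        scaled = TetMesh(
            nodes=mesh.nodes,
            tets=mesh.tets,
            element_density=2.0 * mesh.element_density,
            node_sets=mesh.node_sets,
        )
        frame2 = vf.build_frame(scaled)
        np.testing.assert_allclose(frame1.center_of_mass, frame2.center_of_mass, atol=1e-12)

    def test_body_width_matches_ap_extent(self):
        spec = vf.PhantomSpec(height=22.0, semi_axis_ap=18.0, semi_axis_ml=14.0, voxel=2.0, seed=0)
        vol = vf.make_vertebra_phantom(spec)
        mesh = vf.voxels_to_tets(vol, hu_to_density(vol, CalibrationLine()))
        vf.label_surfaces(mesh)
        frame = vf.build_frame(mesh)
        # oracle: direct extent of the generated node coordinates
        assert frame.body_width == pytest.approx(np.ptp(mesh.nodes[:, 1]), abs=1e-12)
        assert abs(frame.body_width - 36.0) <= 2.0  # within one voxel of 2a

    def test_orthonormal_frame(self, vertebra):
        vertebra["frame"].validate()


class TestControlPoint:
    def test_ten_percent_anterior_offset(self, vertebra):
        frame, mesh = vertebra["frame"], vertebra["mesh"]
        lc = vf.place_control_point(frame, mesh, offset_fraction=0.10)
        proj = frame.center_of_mass + (
            (mesh.nodes[mesh.node_sets["cranial"]].mean(axis=0) - frame.center_of_mass)
            @ frame.transverse_normal
        ) * frame.transverse_normal
        offset = (lc.control_point - proj) @ frame.anterior_direction
        assert offset / frame.body_width == pytest.approx(0.10, rel=1e-9)
        assert lc.offset_fraction == 0.10

    def test_zero_offset_is_centric(self, vertebra):
        frame, mesh = vertebra["frame"], vertebra["mesh"]
        lc = vf.place_control_point(frame, mesh, offset_fraction=0.0)
        rel = lc.control_point - frame.center_of_mass
        assert abs(rel @ frame.anterior_direction) < 1e-9

    def test_control_point_on_cranial_plane(self, vertebra):
        frame, mesh = vertebra["frame"], vertebra["mesh"]
        lc = vf.place_control_point(frame, mesh)
        p0 = mesh.nodes[mesh.node_sets["cranial"]].mean(axis=0)
        assert abs((lc.control_point - p0) @ frame.transverse_normal) < 1e-9

    def test_default_displacement_is_third_of_height(self, vertebra):
        lc = vf.place_control_point(vertebra["frame"], vertebra["mesh"])
        assert lc.total_displacement == pytest.approx(vertebra["frame"].axial_extent / 3.0)

    def test_loadcase_json_round_trip(self, vertebra, tmp_path):
        lc = vf.place_control_point(vertebra["frame"], vertebra["mesh"])
        lc.to_json(tmp_path / "lc.json")
        back = vf.LoadCase.from_json(tmp_path / "lc.json")
        np.testing.assert_allclose(back.control_point, lc.control_point)
        assert back.n_increments == lc.n_increments


class TestInpRoundTrip:
    def test_mesh_and_binned_materials_survive(self, tmp_path):
        vol = vf.make_bar_phantom(4.0, 2.0, 900.0, 1.0)
        rho = hu_to_density(vol, CalibrationLine())
        mesh = vf.voxels_to_tets(vol, rho)
        vf.label_surfaces(mesh)
        rng = np.random.default_rng(1)
        mesh.element_density = rng.uniform(0.4, 1.2, mesh.n_elements)
        cards = vf.assign_materials(mesh.element_density, n_bins=3)
        p = vio.write_inp(mesh, tmp_path / "m.inp", cards)
        mesh2, cards2 = vio.read_inp(p)
        np.testing.assert_allclose(mesh2.nodes, mesh.nodes, atol=1e-8)
        np.testing.assert_array_equal(mesh2.tets, mesh.tets)
        np.testing.assert_array_equal(mesh2.node_sets["cranial"], np.sort(mesh.node_sets["cranial"]))
        np.testing.assert_allclose(cards2.E, cards.E, rtol=1e-8)
        np.testing.assert_allclose(cards2.sigma_y, cards.sigma_y, rtol=1e-8)


class TestErrors:
    def test_empty_surface_rejected(self):
        # two stacked voxels: cranial/caudal fine; flat single-layer slab still has both
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]))
        with pytest.raises(ValueError):
            vf.label_surfaces(mesh)  # tiny tet: cranial/caudal bands overlap

    def test_inverted_element_detected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, -1.0]])
        mesh = TetMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]))
        with pytest.raises(ValueError, match="volume"):
            mesh.validate()
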