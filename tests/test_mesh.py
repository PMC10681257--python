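"""Mesh model, reflection, rigid motion, cropping and normals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import midface3d as mf
from midface3d.mesh import crop_mask, random_rigid


class TestTriangleMesh:
    def test_validation_rejects_bad_faces(self):
        v = np.zeros((3, 3))
        with pytest.raises(mf.MeshError):
            mf.TriangleMesh(v, [[0, 1, 3]])  # out of range
        with pytest.raises(mf.MeshError):
            mf.TriangleMesh(v, [[0, 1, 1]])  # repeated vertex
        with pytest.raises(mf.MeshError, match="empty"):
            mf.TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int))


class TestMirror:
    def test_symmetric_mesh_maps_onto_itself(self, small_face, frame):
        mesh, truth = small_face
        mirrored, iso, _ = mf.mirror_mesh(mesh, frame)
        # mirrored vertex i must equal the original's contralateral partner
        np.testing.assert_allclose(
            mirrored.vertices, mesh.vertices[truth.partner], atol=1e-9
        )

    def test_reflection_determinant(self, small_face, frame):
        mesh, _ = small_face
        _, iso, _ = mf.mirror_mesh(mesh, frame)
        assert np.isclose(np.linalg.det(iso.rotation), -1.0, atol=1e-12)

    def test_double_mirror_is_identity(self, bumped_face, frame):
        mesh, _ = bumped_face
        m1, iso1, _ = mf.mirror_mesh(mesh, frame)
        m2, iso2, _ = mf.mirror_mesh(m1, frame)
        np.testing.assert_allclose(m2.vertices, mesh.vertices, atol=1e-12)
        net = iso2.compose(iso1)
        np.testing.assert_allclose(net.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(net.translation, 0.0, atol=1e-12)

    def test_isometry_maps_vertex_i_to_mirrored_i(self, bumped_face, frame):
        mesh, _ = bumped_face
        mirrored, iso, _ = mf.mirror_mesh(mesh, frame)
        np.testing.assert_allclose(
            iso.apply(mesh.vertices), mirrored.vertices, atol=1e-12
        )

    def test_winding_reversed_keeps_normals_outward(self, small_face, frame):
        mesh, _ = small_face
        mirrored, _, _ = mf.mirror_mesh(mesh, frame)
        # face normals of this heightfield point along +x both before and after
        assert (mf.vertex_normals(mesh)[:, 0] > 0).all()
        assert (mf.vertex_normals(mirrored)[:, 0] > 0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_reflection_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3)) * 40
        mesh = mf.TriangleMesh(pts, [[0, 1, 2]])
        mirrored, _, _ = mf.mirror_mesh(mesh, mf.CanonicalFrame())
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d1 = np.linalg.norm(
            mirrored.vertices[:, None] - mirrored.vertices[None], axis=2
        )
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestApplyTransform:
    def test_identity_and_translation(self, toy_grid):
        same = mf.apply_transform(toy_grid, mf.RigidTransform())
        np.testing.assert_array_equal(same.vertices, toy_grid.vertices)
        shifted = mf.apply_transform(
            toy_grid, mf.RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        )
        np.testing.assert_allclose(
            shifted.vertices[:, 0], toy_grid.vertices[:, 0] + 1.0
        )

    def test_rigid_round_trip(self, toy_grid):
        rng = np.random.default_rng(4)
        t = random_rigid(25.0, 8.0, rng)
        back = mf.apply_transform(mf.apply_transform(toy_grid, t), t.inverse())
        np.testing.assert_allclose(back.vertices, toy_grid.vertices, atol=1e-12)

    def test_non_orthonormal_matrix_rejected(self):
        with pytest.raises(mf.MeshError, match="orthonormal"):
            mf.RigidTransform(np.diag([2.0, 1.0, 1.0]), np.zeros(3))


class TestCropBox:
    def test_identity_crop(self, toy_grid, frame):
        lim = [[-10, 10]] * 3
        cropped, _, index_map = mf.crop_box(toy_grid, frame, lim)
        assert cropped.n_faces == toy_grid.n_faces
        np.testing.assert_array_equal(index_map, np.arange(9))

    def test_left_half_of_two_by_two_grid(self, toy_grid, frame):
        # toy grid spans y,z in [0,2]; keep z <= 1: one column of squares
        cropped, _, _ = mf.crop_box(
            toy_grid, frame, [[-10, 10], [-10, 10], [-10, 1.0]]
        )
        assert cropped.n_faces == 4
        assert cropped.n_vertices == 6

    def test_selection_remap_and_round_trip(self, toy_grid, frame):
        sel = mf.VertexSelection("s", [0, 4, 8])
        cropped, sels, index_map = mf.crop_box(
            toy_grid, frame, [[-10, 10], [-10, 10], [-10, 1.0]], [sel]
        )
        # vertex 8 (z=2) is cropped away; 0 and 4 survive remapped
        assert len(sels[0]) == 2
        old = np.flatnonzero(np.isin(index_map, sels[0].indices))
        np.testing.assert_array_equal(old, [0, 4])
        # output faces are a subset of input faces by coordinates
        in_tris = {tuple(map(tuple, t)) for t in np.round(toy_grid.triangles(), 9)}
        for t in np.round(cropped.triangles(), 9):
            assert tuple(map(tuple, t)) in in_tris

    def test_empty_crop_errors(self, toy_grid, frame):
        with pytest.raises(mf.MeshError, match="empty crop"):
            mf.crop_box(toy_grid, frame, [[5, 6]] * 3)

    def test_unilateral_crop_is_laterally_asymmetric(self, bumped_face, frame):
        mesh, truth = bumped_face
        cropped, _, _ = mf.crop_box(
            mesh, frame, [[-1e9, 1e9], [-1e9, 1e9], [-30.0, 1e9]]
        )
        z = cropped.vertices[:, 2]
        assert abs(z.max() + z.min()) > 10.0  # extents unbalanced about z=0


class TestVertexNormals:
    def test_flat_grid_faces_plus_x(self, toy_grid):
        np.testing.assert_allclose(
            mf.vertex_normals(toy_grid), np.tile([1.0, 0, 0], (9, 1)), atol=1e-12
        )

    def test_sphere_normals_are_radial(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        mesh = mf.TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        n = mf.vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        angles = np.degrees(
            np.arccos(np.clip(np.einsum("ij,ij->i", n, radial), -1, 1))
        )
        assert angles.max() < 5.0

    def test_winding_flip_negates_normals(self, toy_grid):
        flipped = mf.TriangleMesh(toy_grid.vertices, toy_grid.faces[:, ::-1])
        np.testing.assert_allclose(
            mf.vertex_normals(flipped), -mf.vertex_normals(toy_grid), atol=1e-12
        )

    def test_isolated_vertex_gets_zero_normal(self):
        mesh = mf.TriangleMesh(
            [[0, 0, 0], [0, 1, 0], [0, 0, 1], [5, 5, 5]], [[0, 1, 2]]
        )
        assert np.linalg.norm(mf.vertex_normals(mesh)[3]) == 0.0


class TestRandomRigid:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_properness(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(3.0, 3.0, rng)
        assert np.isclose(np.linalg.det(t.rotation), 1.0, atol=1e-9)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(t.rotation) - 1) / 2, -1, 1))
        )
        assert angle <= 3.0 + 1e-9
        assert np.linalg.norm(t.translation) <= 3.0 + 1e-12
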