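"""Exact closest-point search and mirror-ICP superimposition."""

import numpy as np
import pytest

import midface3d as mf
from midface3d.mesh import random_rigid
from midface3d.register import SurfaceIndex, closest_point_on_surface

from conftest import oracle_closest_distance


@pytest.fixture(scope="module")
def small_face_pair():
    return mf.generate_face(mf.FaceSpec(ny=40, nz=36))


class TestClosestPoint:
    def test_point_above_triangle(self):
        mesh = mf.TriangleMesh(
            [[-1, -1, 0], [1, -1, 0], [0, 1, 0]], [[0, 1, 2]]
        )
        c = closest_point_on_surface([0.0, 0.0, 2.0], mesh)
        assert c.distance == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(c.point, [0, 0, 0], atol=1e-12)

    def test_point_on_vertex_has_zero_distance(self, toy_grid):
        c = closest_point_on_surface(toy_grid.vertices[0], toy_grid)
        assert c.distance == pytest.approx(0.0, abs=1e-12)
        assert c.on_boundary  # grid corner is on the boundary

    def test_interior_vertex_not_boundary(self, toy_grid):
        c = closest_point_on_surface(toy_grid.vertices[4], toy_grid)
        assert c.distance == pytest.approx(0.0, abs=1e-12)
        assert not c.on_boundary

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        verts = rng.normal(size=(30, 3)) * 10
        faces = rng.integers(0, 30, size=(50, 3))
        faces = faces[
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        ]
        mesh = mf.TriangleMesh(verts, faces)
        index = SurfaceIndex(mesh)
        points = rng.normal(size=(40, 3)) * 15
        dist, _, _, _ = index.query(points)
        for p, d in zip(points, dist):
            assert d == pytest.approx(oracle_closest_distance(p, mesh), abs=1e-9)

    def test_matches_oracle_on_face_surface(self, small_face_pair):
        mesh, _ = small_face_pair
        sub, _, _ = mf.crop_box(  # keep the oracle loop affordable
            mesh, mf.CanonicalFrame(), [[-1e9, 1e9], [-10, 10], [-10, 10]]
        )
        index = SurfaceIndex(sub)
        rng = np.random.default_rng(5)
        points = sub.vertices[rng.choice(sub.n_vertices, 15, replace=False)]
        points = points + rng.normal(size=points.shape) * 3
        dist, _, _, _ = index.query(points)
        for p, d in zip(points, dist):
            assert d == pytest.approx(oracle_closest_distance(p, sub), abs=1e-9)


class TestICP:
    def test_defaults_match_superimposition_settings(self):
        cfg = mf.ICPConfig()
        assert cfg.overlap_fraction == 1.0
        assert cfg.sampling_fraction == 1.0
        assert cfg.metric == "point_to_plane"
        assert cfg.exclude_overhang is True

    def test_config_validation(self):
        with pytest.raises(ValueError):
            mf.ICPConfig(overlap_fraction=0.0)
        with pytest.raises(ValueError):
            mf.ICPConfig(metric="nonsense")

    def test_config_from_yaml(self, tmp_path):
        p = tmp_path / "icp.yaml"
        p.write_text("overlap_fraction: 0.9\nmetric: point_to_point\n")
        cfg = mf.ICPConfig.from_file(p)
        assert cfg.overlap_fraction == 0.9
        assert cfg.metric == "point_to_point"

    def test_identity_fixed_point(self, small_face_pair):
        mesh, _ = small_face_pair
        res = mf.icp_align(mesh, mesh)
        assert res.rms < 1e-9
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, 0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_recovers_known_rigid_displacement(self, small_face_pair, seed):
        mesh, _ = small_face_pair
        rng = np.random.default_rng(seed)
        motion = random_rigid(8.0, 8.0, rng, about=mesh.centroid())
        moved = mf.apply_transform(mesh, motion)
        res = mf.icp_align(moved, mesh)
        assert res.rms < 1e-4
        net = res.transform.compose(motion)
        np.testing.assert_allclose(net.rotation, np.eye(3), atol=1e-5)
        realigned = mf.apply_transform(moved, res.transform)
        assert np.abs(realigned.vertices - mesh.vertices).max() < 1e-4

    def test_transform_is_proper_and_trace_settles(self, small_face_pair):
        mesh, _ = small_face_pair
        rng = np.random.default_rng(7)
        moved = mf.apply_transform(
            mesh, random_rigid(5.0, 5.0, rng, about=mesh.centroid())
        )
        res = mf.icp_align(moved, mesh)
        assert np.isclose(np.linalg.det(res.transform.rotation), 1.0, atol=1e-9)
        trace = res.residual_trace[3:]
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_point_to_point_metric_also_recovers(self, small_face_pair):
        mesh, _ = small_face_pair
        rng = np.random.default_rng(2)
        motion = random_rigid(5.0, 5.0, rng, about=mesh.centroid())
        moved = mf.apply_transform(mesh, motion)
        res = mf.icp_align(moved, mesh, mf.ICPConfig(metric="point_to_point"))
        realigned = mf.apply_transform(moved, res.transform)
        # point-to-point converges linearly and stalls earlier than
        # point-to-plane; it must still land well inside the perturbation
        assert np.abs(realigned.vertices - mesh.vertices).max() < 0.2
        assert res.rms < 0.05


class TestMirrorFit:
    def test_symmetric_face_limit(self, small_face_pair, frame):
        mesh, truth = small_face_pair
        aligned, net, res = mf.mirror_fit(mesh, frame)
        assert np.isclose(np.linalg.det(net.rotation), -1.0, atol=1e-9)
        index = SurfaceIndex(mesh)
        dist, _, _, _ = index.query(aligned.vertices)
        assert dist.max() < 1e-4

    def test_bump_elevates_footprint_mad(self, bumped_face, frame):
        mesh, truth = bumped_face
        aligned, _, _ = mf.mirror_fit(mesh, frame)
        dmap = mf.distance_map(mesh, aligned)
        foot = mf.area_mad(dmap, truth.footprints["bump0"]).mad
        y, z = truth.vertex_yz()
        far = np.flatnonzero((y >= 40) & (np.abs(z) <= 40))
        background = mf.area_mad(dmap, mf.VertexSelection("bg", far)).mad
        assert foot > 5.0 * background

    def test_deterministic_rerun(self, bumped_face, frame):
        mesh, _ = bumped_face
        _, net1, _ = mf.mirror_fit(mesh, frame)
        _, net2, _ = mf.mirror_fit(mesh, frame)
        np.testing.assert_allclose(net1.rotation, net2.rotation, atol=1e-10)
        np.testing.assert_allclose(net1.translation, net2.translation, atol=1e-10)

    def test_pose_invariance_of_optimum(self, bumped_face, frame):
        """Rigid start-pose changes within the basin leave the aligned
        result essentially unchanged — the basis of the reproducibility
        protocol."""
        mesh, _ = bumped_face
        aligned, _, _ = mf.mirror_fit(mesh, frame)
        mirrored, refl, _ = mf.mirror_mesh(mesh, frame)
        rng = np.random.default_rng(9)
        start = random_rigid(5.0, 5.0, rng, about=mirrored.centroid())
        res = mf.icp_align(mf.apply_transform(mirrored, start), mesh)
        realigned = mf.apply_transform(
            mf.apply_transform(mirrored, start), res.transform
        )
        assert (
            np.linalg.norm(realigned.vertices - aligned.vertices, axis=1).max()
            < 1e-3
        )
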