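"""Shared fixtures: small synthetic faces, toy meshes, and the independent
point-to-triangle oracle used to certify the exact closest-point search."""

from __future__ import annotations

import numpy as np
import pytest

import midface3d as mf


@pytest.fixture(scope="session")
def frame() -> mf.CanonicalFrame:
    return mf.CanonicalFrame()


@pytest.fixture(scope="session")
def small_spec() -> mf.FaceSpec:
    """Coarse face grid for fast unit tests (~1400 vertices)."""
    return mf.FaceSpec(ny=40, nz=36)


@pytest.fixture(scope="session")
def small_face(small_spec):
    return mf.generate_face(small_spec)


@pytest.fixture(scope="session")
def bumped_face(small_spec):
    """Small face with a single 1 mm bump on the subject's right cheek."""
    mesh, truth = mf.generate_face(small_spec)
    return mf.inject_asymmetry(
        mesh,
        truth,
        mf.AsymmetrySpec(
            bumps=(mf.GaussianFeature(y=-5.0, z=-30.0, amplitude=1.0, width=10.0),),
            seed=3,
        ),
    )


@pytest.fixture()
def toy_grid() -> mf.TriangleMesh:
    """Flat 3x3-vertex grid in the x=0 plane: 2x2 squares, 8 triangles.

    Vertex k = (0, row, col) for rows/cols in {0, 1, 2}."""
    rows, cols = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
    vertices = np.column_stack(
        [np.zeros(9), rows.ravel(), cols.ravel()]
    )
    idx = np.arange(9).reshape(3, 3)
    v00, v01 = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
    v10, v11 = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    return mf.TriangleMesh(vertices, faces)


def oracle_closest_distance(point: np.ndarray, mesh: mf.TriangleMesh) -> float:
    """Brute-force closest-point distance, structured independently of the
    library's region-based routine: for every face take the minimum over
    the clamped plane projection, the three clamped edge projections, and
    the three corners."""
    p = np.asarray(point, float)
    best = np.inf
    for tri in mesh.triangles():
        a, b, c = tri
        candidates = [a, b, c]
        # plane projection, accepted only if barycentrically inside
        n = np.cross(b - a, c - a)
        nn = n @ n
        if nn > 0:
            proj = p - ((p - a) @ n / nn) * n
            t_mat = np.column_stack([b - a, c - a])
            uv, *_ = np.linalg.lstsq(t_mat, proj - a, rcond=None)
            if uv[0] >= -1e-12 and uv[1] >= -1e-12 and uv.sum() <= 1 + 1e-12:
                candidates.append(proj)
        for e0, e1 in ((a, b), (b, c), (c, a)):
            d = e1 - e0
            t = np.clip((p - e0) @ d / (d @ d), 0.0, 1.0)
            candidates.append(e0 + t * d)
        best = min(best, min(np.linalg.norm(p - q) for q in candidates))
    return float(best)
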