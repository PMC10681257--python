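"""Superimposition of the mirrored duplicate onto the original mesh.

The registration follows the classic mirror-and-fit recipe: reflect the
mesh, then align the reflected copy back onto the original with iterative
closest point (ICP) using a point-to-plane metric, exact nearest-neighbour
(vertex-to-surface) correspondences, 100% overlap and sampling, and
exclusion of correspondences that land on the target boundary ("overhang"
regions).  The original mesh never moves; only the mirrored copy does.

Exactness of the closest-point search matters: the spatial index (a k-d
tree over triangle centroids) is used only to *prune* triangles that are
provably farther than an already-established upper bound, so the returned
correspondence minimises the true point-to-triangle distance over all
faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .mesh import (
    CanonicalFrame,
    ImproperIsometry,
    MeshError,
    RigidTransform,
    TriangleMesh,
    VertexSelection,
    apply_transform,
    mirror_mesh,
)

__all__ = [
    "RegistrationError",
    "ICPConfig",
    "Correspondence",
    "ICPResult",
    "SurfaceIndex",
    "closest_point_on_surface",
    "icp_align",
    "mirror_fit",
]

# closest points nearer than this to an edge/vertex count as lying on it
_ON_FEATURE_TOL = 1e-9


class RegistrationError(RuntimeError):
    """ICP failure: no usable correspondences or a non-finite update."""


@dataclass(frozen=True)
class ICPConfig:
    """ICP settings; the defaults are the full-overlap, point-to-plane,
    exact-NN, full-sampling, overhang-excluding configuration used for
    mirror-image superimposition.

    Attributes
    ----------
    overlap_fraction : float
        Fraction of (non-excluded) correspondences kept each iteration,
        smallest distances first.  1.0 keeps all.
    sampling_fraction : float
        Fraction of moving vertices used, drawn once per run with ``seed``.
    metric : str
        ``point_to_plane`` (residual along the target normal) or
        ``point_to_point`` (full Euclidean residual).
    exclude_overhang : bool
        Drop correspondences whose closest point lies on a boundary
        edge/vertex of the target surface.
    convergence_tol : float
        Stop when the RMS residual changes by less than this (mm).
    """

    overlap_fraction: float = 1.0
    sampling_fraction: float = 1.0
    metric: str = "point_to_plane"
    exclude_overhang: bool = True
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.metric not in ("point_to_plane", "point_to_point"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "ICPConfig":
        """Load settings from a YAML (or JSON, a YAML subset) mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class Correspondence:
    """One source point's exact closest point on the target surface."""

    source_index: int
    point: np.ndarray
    face_index: int
    normal: np.ndarray
    distance: float
    on_boundary: bool


@dataclass
class ICPResult:
    """Outcome of one ICP run.

    ``transform`` maps the moving mesh's input coordinates onto the fixed
    mesh (it already includes the ``initial`` transform supplied).
    """

    transform: RigidTransform
    iterations: int
    rms: float
    residual_trace: list[float] = field(default_factory=list)
    n_excluded_overhang: int = 0


# ---------------------------------------------------------------------------
# exact point-to-triangle distance (vectorised, Ericson-style regions)
# ---------------------------------------------------------------------------

# region codes: 0 face interior, 1/2/3 vertices a/b/c, 4/5/6 edges ab/bc/ca
_REGION_FACE = 0
_REGION_VA, _REGION_VB, _REGION_VC = 1, 2, 3
_REGION_AB, _REGION_BC, _REGION_CA = 4, 5, 6


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on each triangle for each paired query point.

    Parameters: ``points`` (k, 3) and ``tri`` (k, 3, 3).  Returns closest
    points (k, 3) and region codes (k,).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    region = np.full(len(points), -1, dtype=np.int8)
    todo = np.ones(len(points), dtype=bool)

    def settle(mask, value, code):
        m = todo & mask
        out[m] = value[m] if value.ndim == 2 else value
        region[m] = code
        todo[m] = False

    settle((d1 <= 0) & (d2 <= 0), a, _REGION_VA)
    settle((d3 >= 0) & (d4 <= d3), b, _REGION_VB)
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab, _REGION_AB)
    settle((d6 >= 0) & (d5 <= d6), c, _REGION_VC)
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ca = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ca[:, None] * ac, _REGION_CA)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + w_bc[:, None] * (c - b),
        _REGION_BC,
    )
    if todo.any():
        denom = va + vb + vc
        v = (vb / denom)[:, None]
        w = (vc / denom)[:, None]
        inner = a + v * ab + w * ac
        out[todo] = inner[todo]
        region[todo] = _REGION_FACE
    return out, region


class SurfaceIndex:
    """Spatial index over a mesh's triangles for exact closest-point queries.

    Pruning is conservative: after an upper bound U on the distance is
    established from the triangle with the nearest centroid, only triangles
    whose centroid lies within U + r_max (r_max = largest centroid-to-corner
    radius) can possibly do better, so scanning exactly that ball preserves
    exactness.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise MeshError("empty mesh")
        self.mesh = mesh
        self.tri = mesh.triangles()
        self.centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max(
            axis=1
        )
        self.r_max = float(self.radii.max())
        self.tree = cKDTree(self.centroids)
        fn = np.cross(
            self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0]
        )
        norms = np.linalg.norm(fn, axis=1)
        norms[norms == 0] = 1.0
        self.face_normals = fn / norms[:, None]
        self._build_boundary_tables(mesh)

    def _build_boundary_tables(self, mesh: TriangleMesh) -> None:
        f = mesh.faces
        # edges per face in region-code order: ab, bc, ca
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        edge_boundary = (counts == 1)[inverse]  # (3m,) in ab|bc|ca blocks
        m = mesh.n_faces
        self.face_edge_boundary = np.stack(
            [edge_boundary[:m], edge_boundary[m : 2 * m], edge_boundary[2 * m :]],
            axis=1,
        )
        vb = np.zeros(mesh.n_vertices, dtype=bool)
        vb[edges[edge_boundary].ravel()] = True
        self.face_vertex_boundary = vb[f]

    def _boundary_flags(self, face_idx: np.ndarray, region: np.ndarray) -> np.ndarray:
        flags = np.zeros(len(face_idx), dtype=bool)
        for code, col in ((_REGION_AB, 0), (_REGION_BC, 1), (_REGION_CA, 2)):
            m = region == code
            flags[m] = self.face_edge_boundary[face_idx[m], col]
        for code, col in ((_REGION_VA, 0), (_REGION_VB, 1), (_REGION_VC, 2)):
            m = region == code
            flags[m] = self.face_vertex_boundary[face_idx[m], col]
        return flags

    def query(self, points: np.ndarray, chunk: int = 4096):
        """Exact closest point on the surface for each query point.

        Returns (distances, closest_points, face_indices, boundary_flags).
        Ties between faces are broken toward the smallest face index, which
        keeps the whole pipeline deterministic.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        dist = np.empty(n)
        closest = np.empty((n, 3))
        fidx = np.empty(n, dtype=np.int64)
        flags = np.empty(n, dtype=bool)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            self._query_chunk(pts[sl], dist, closest, fidx, flags, start)
        return dist, closest, fidx, flags

    def _query_chunk(self, pts, dist, closest, fidx, flags, offset):
        k = len(pts)
        _, seed_idx = self.tree.query(pts)
        seed_cp, seed_region = _closest_on_triangles(pts, self.tri[seed_idx])
        upper = np.linalg.norm(pts - seed_cp, axis=1)
        lists = self.tree.query_ball_point(pts, upper + self.r_max + 1e-12)
        lengths = np.fromiter((len(l) for l in lists), dtype=np.int64, count=k)
        cand = np.fromiter(
            (j for l in lists for j in l), dtype=np.int64, count=int(lengths.sum())
        )
        owner = np.repeat(np.arange(k), lengths)
        cp, region = _closest_on_triangles(pts[owner], self.tri[cand])
        d = np.linalg.norm(pts[owner] - cp, axis=1)
        # deterministic per-point argmin: order by (owner, distance, face index)
        order = np.lexsort((cand, d, owner))
        owner_sorted = owner[order]
        first = np.ones(len(order), dtype=bool)
        first[1:] = owner_sorted[1:] != owner_sorted[:-1]
        pick = order[first]
        which = owner[pick]
        dist[offset + which] = d[pick]
        closest[offset + which] = cp[pick]
        best_face = cand[pick]
        best_region = region[pick]
        fidx[offset + which] = best_face
        flags[offset + which] = self._boundary_flags(best_face, best_region)
        # points whose candidate list was somehow empty fall back to the seed
        missing = lengths == 0
        if missing.any():
            mi = np.flatnonzero(missing)
            dist[offset + mi] = upper[mi]
            closest[offset + mi] = seed_cp[mi]
            fidx[offset + mi] = seed_idx[mi]
            flags[offset + mi] = self._boundary_flags(
                seed_idx[mi], seed_region[mi]
            )


def closest_point_on_surface(
    point: np.ndarray, index: SurfaceIndex | TriangleMesh
) -> Correspondence:
    """Exact closest point on a surface for a single query point."""
    if isinstance(index, TriangleMesh):
        index = SurfaceIndex(index)
    p = np.asarray(point, dtype=np.float64).reshape(1, 3)
    dist, cp, fi, fl = index.query(p)
    return Correspondence(
        source_index=0,
        point=cp[0],
        face_index=int(fi[0]),
        normal=index.face_normals[int(fi[0])],
        distance=float(dist[0]),
        on_boundary=bool(fl[0]),
    )


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def _rotation_from_omega(omega: np.ndarray) -> np.ndarray:
    """Exact rotation for the small-angle update vector (Rodrigues)."""
    angle = np.linalg.norm(omega)
    if angle < 1e-300:
        return np.eye(3)
    axis = omega / angle
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _solve_point_to_plane(p, q, n):
    """Linearised point-to-plane least squares -> (omega, translation)."""
    r = np.einsum("ij,ij->i", p - q, n)
    jac = np.hstack([np.cross(p, n), n])
    h = jac.T @ jac
    g = jac.T @ r
    try:
        x = np.linalg.solve(h, -g)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(h, -g, rcond=None)[0]
    return x[:3], x[3:]


def _solve_point_to_point(p, q):
    """Kabsch/Umeyama rigid fit of p onto q -> (R, t)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    u, _, vt = np.linalg.svd((p - pc).T @ (q - qc))
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    return rot, qc - rot @ pc


def icp_align(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    config: ICPConfig | None = None,
    initial: RigidTransform | None = None,
    fixed_index: SurfaceIndex | None = None,
) -> ICPResult:
    """Rigidly align ``moving`` onto the surface of ``fixed``.

    Each iteration builds exact vertex-to-surface correspondences, drops
    those flagged on the target boundary (overhang exclusion), optionally
    trims to the closest ``overlap_fraction``, solves the linearised
    point-to-plane system (or a Kabsch fit for the point-to-point metric),
    and applies the incremental rigid update.  Iteration stops when the RMS
    residual changes by less than ``convergence_tol`` mm.
    """
    config = config or ICPConfig()
    transform = initial or RigidTransform.identity()
    index = fixed_index if fixed_index is not None else SurfaceIndex(fixed)

    pts = moving.vertices
    if config.sampling_fraction < 1.0:
        rng = np.random.default_rng(config.seed)
        n_keep = max(6, int(round(config.sampling_fraction * len(pts))))
        sample = np.sort(rng.choice(len(pts), size=n_keep, replace=False))
        pts = pts[sample]

    trace: list[float] = []
    prev_rms = np.inf
    n_excluded = 0
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        p = transform.apply(pts)
        dist, cp, fi, boundary = index.query(p)
        use = np.ones(len(p), dtype=bool)
        if config.exclude_overhang:
            use &= ~boundary
            n_excluded = int(boundary.sum())
        if not use.any():
            raise RegistrationError("no usable correspondences")
        if config.overlap_fraction < 1.0:
            kept = np.flatnonzero(use)
            n_keep = max(6, int(round(config.overlap_fraction * len(kept))))
            order = kept[np.argsort(dist[kept], kind="stable")]
            use = np.zeros_like(use)
            use[order[:n_keep]] = True

        pu, qu = p[use], cp[use]
        nu = index.face_normals[fi[use]]
        if config.metric == "point_to_plane":
            res = np.einsum("ij,ij->i", pu - qu, nu)
        else:
            res = np.linalg.norm(pu - qu, axis=1)
        rms = float(np.sqrt(np.mean(res**2)))
        trace.append(rms)
        if abs(prev_rms - rms) < config.convergence_tol:
            break
        prev_rms = rms

        if config.metric == "point_to_plane":
            omega, t = _solve_point_to_plane(pu, qu, nu)
            rot = _rotation_from_omega(omega)
        else:
            rot, t = _solve_point_to_point(pu, qu)
        if not (np.isfinite(rot).all() and np.isfinite(t).all()):
            raise RegistrationError(
                f"non-finite ICP update at iteration {iteration}; trace={trace}"
            )
        transform = RigidTransform(rot, t).compose(transform)

    return ICPResult(
        transform=transform,
        iterations=iteration,
        rms=trace[-1],
        residual_trace=trace,
        n_excluded_overhang=n_excluded,
    )


def mirror_fit(
    original: TriangleMesh,
    frame: CanonicalFrame,
    selections: list[VertexSelection] | None = None,
    config: ICPConfig | None = None,
) -> tuple[TriangleMesh, ImproperIsometry, ICPResult]:
    """Mirror ``original`` and best-fit the mirrored copy back onto it.

    Returns the aligned mirrored mesh (index-corresponding with the
    original), the net improper isometry (ICP rigid motion composed with
    the reflection, det −1), and the ICP diagnostics.  The original mesh is
    never moved.
    """
    mirrored, reflection, _ = mirror_mesh(original, frame, selections)
    result = icp_align(mirrored, original, config)
    aligned = apply_transform(mirrored, result.transform)
    net = result.transform.compose(reflection)
    if not isinstance(net, ImproperIsometry):  # pragma: no cover - safety net
        raise RegistrationError("net mirror-fit map lost its orientation reversal")
    return aligned, net, result
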