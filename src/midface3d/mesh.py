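"""Core mesh data model and rigid/improper isometries.

The whole pipeline hinges on one bookkeeping rule: a mesh and its mirrored
duplicate share vertex indices, so vertex ``i`` of the mirrored copy is the
contralateral partner of vertex ``i`` of the original.  Every operation in
this module therefore preserves vertex order, and cropping returns an
explicit old-to-new index map so selections can follow the surviving
vertices.

Units are millimetres throughout; angles are degrees at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MeshError",
    "TriangleMesh",
    "CanonicalFrame",
    "VertexSelection",
    "RigidTransform",
    "ImproperIsometry",
    "mirror_mesh",
    "apply_transform",
    "crop_box",
    "crop_mask",
    "vertex_normals",
    "random_rigid",
]

_ORTHO_TOL = 1e-9


class MeshError(ValueError):
    """Raised for invalid meshes, transforms, or selections."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh with order-significant vertices (mm).

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Counter-clockwise winding defines the outward normal.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if v.shape[0] == 0:
            raise MeshError("empty mesh")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise MeshError("face index out of range")
            if (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            ).any():
                raise MeshError("face repeats a vertex")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        """Mean of the vertex positions (not area-weighted)."""
        return self.vertices.mean(axis=0)

    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) coordinates of each face's corners."""
        return self.vertices[self.faces]


def _check_axes(axes: np.ndarray) -> None:
    if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
        raise MeshError("frame axes must be orthonormal")
    if np.linalg.det(axes) < 0:
        raise MeshError("frame must be right-handed (det +1)")


@dataclass(frozen=True)
class CanonicalFrame:
    """Right-handed anatomical frame.

    X points anteriorly, Y superiorly (vertical axis) and Z laterally toward
    the subject's left, so the midsagittal plane of an ideally oriented face
    has normal Z.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        a = np.asarray(self.axes, dtype=np.float64).reshape(3, 3)
        _check_axes(a)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", a)

    @property
    def x(self) -> np.ndarray:  # anteroposterior
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:  # vertical
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:  # lateral, + = subject's left
        return self.axes[2]

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates."""
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.axes.T

    def from_frame(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=np.float64) @ self.axes + self.origin


@dataclass(frozen=True)
class VertexSelection:
    """Named, sorted subset of a mesh's vertex indices.

    A selection survives mirroring unchanged: the same indices simply land
    at the contralateral location.
    """

    name: str
    indices: np.ndarray
    mesh_id: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64).ravel())
        if idx.size and idx[0] < 0:
            raise MeshError(f"selection {self.name!r} has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate_for(self, mesh: TriangleMesh) -> None:
        if len(self.indices) and self.indices[-1] >= mesh.n_vertices:
            raise MeshError(
                f"selection {self.name!r} references vertex "
                f"{int(self.indices[-1])} of a {mesh.n_vertices}-vertex mesh"
            )

    def remap(self, index_map: np.ndarray) -> "VertexSelection":
        """Follow an old->new index map, silently dropping removed vertices."""
        mapped = index_map[self.indices]
        return replace(self, indices=mapped[mapped >= 0])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation det +1)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    _expected_det = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise MeshError("matrix is not orthonormal")
        if abs(np.linalg.det(r) - self._expected_det) > 1e-6:
            raise MeshError(
                f"determinant must be {self._expected_det:+.0f}, "
                f"got {np.linalg.det(r):.6f}"
            )
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.rotation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform | ImproperIsometry"):
        """Return self ∘ other (apply ``other`` first)."""
        rot = self.rotation @ other.rotation
        tra = self.rotation @ other.translation + self.translation
        cls = RigidTransform if np.linalg.det(rot) > 0 else ImproperIsometry
        return cls(rot, tra)

    def inverse(self):
        rinv = self.rotation.T
        return type(self)(rinv, -rinv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass(frozen=True)
class ImproperIsometry(RigidTransform):
    """Orientation-reversing isometry (det −1): reflection ∘ rigid motion.

    This is the net map relating an original mesh to its aligned mirrored
    duplicate.
    """

    _expected_det = -1.0

    @classmethod
    def reflection(cls, point: np.ndarray, normal: np.ndarray) -> "ImproperIsometry":
        """Householder reflection across the plane through ``point`` with
        unit ``normal``."""
        n = np.asarray(normal, dtype=np.float64).reshape(3)
        n = n / np.linalg.norm(n)
        p = np.asarray(point, dtype=np.float64).reshape(3)
        m = np.eye(3) - 2.0 * np.outer(n, n)
        return cls(m, 2.0 * np.dot(p, n) * n)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def mirror_mesh(
    mesh: TriangleMesh,
    frame: CanonicalFrame,
    selections: list[VertexSelection] | None = None,
) -> tuple[TriangleMesh, ImproperIsometry, list[VertexSelection]]:
    """Duplicate and mirror a mesh, carrying selections over index-identical.

    The mirror plane passes through the mesh centroid with normal = the
    frame's lateral (Z) axis.  Any other choice differs only by a rigid
    motion, which the subsequent ICP alignment absorbs.  Face winding is
    reversed so outward normals stay outward.

    Returns
    -------
    mirrored : TriangleMesh
        Vertex ``i`` is the reflection of vertex ``i`` of the input.
    isometry : ImproperIsometry
        Maps original vertex ``i`` exactly onto mirrored vertex ``i``.
    selections : list of VertexSelection
        The input selections, unchanged (indices are preserved).
    """
    refl = ImproperIsometry.reflection(mesh.centroid(), frame.z)
    mirrored = TriangleMesh(refl.apply(mesh.vertices), mesh.faces[:, ::-1])
    carried = list(selections) if selections else []
    for sel in carried:
        sel.validate_for(mesh)
    return mirrored, refl, carried


def apply_transform(
    mesh: TriangleMesh, transform: RigidTransform | ImproperIsometry
) -> TriangleMesh:
    """Apply an isometry to every vertex; winding flips iff det = −1."""
    faces = mesh.faces[:, ::-1] if transform.det < 0 else mesh.faces
    return TriangleMesh(transform.apply(mesh.vertices), faces)


def crop_box(
    mesh: TriangleMesh,
    frame: CanonicalFrame,
    limits: np.ndarray,
    selections: list[VertexSelection] | None = None,
) -> tuple[TriangleMesh, list[VertexSelection], np.ndarray]:
    """Crop to the axis-aligned box ``limits`` in frame coordinates.

    ``limits`` is (3, 2): per frame axis [min, max] in mm; use ±inf for
    unbounded sides.  A face is kept only when all three of its vertices lie
    inside the closed box — no re-meshing occurs at the crop planes, so the
    cut is ragged at the one-edge-length scale, which is negligible against
    the centimetre-scale crops this emulates.

    Returns the cropped mesh, the selections remapped through the index map
    (indices of removed vertices silently dropped), and the old->new index
    map itself (-1 marks removed vertices).
    """
    lim = np.asarray(limits, dtype=np.float64).reshape(3, 2)
    if (lim[:, 0] > lim[:, 1]).any():
        raise MeshError("crop box limits must satisfy min <= max")
    coords = frame.to_frame(mesh.vertices)
    inside = ((coords >= lim[:, 0]) & (coords <= lim[:, 1])).all(axis=1)
    return crop_mask(mesh, inside, selections)


def crop_mask(
    mesh: TriangleMesh,
    vertex_mask: np.ndarray,
    selections: list[VertexSelection] | None = None,
) -> tuple[TriangleMesh, list[VertexSelection], np.ndarray]:
    """Keep exactly the faces whose three vertices are all flagged.

    Shared machinery behind :func:`crop_box` and the freeform crop
    emulation; returns (cropped mesh, remapped selections, old->new map).
    """
    inside = np.asarray(vertex_mask, dtype=bool).reshape(mesh.n_vertices)
    keep_face = inside[mesh.faces].all(axis=1)
    if not keep_face.any():
        raise MeshError("empty crop")
    faces = mesh.faces[keep_face]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[faces.ravel()] = True
    index_map = np.full(mesh.n_vertices, -1, dtype=np.int64)
    index_map[used] = np.arange(int(used.sum()))
    cropped = TriangleMesh(mesh.vertices[used], index_map[faces])
    remapped = [s.remap(index_map) for s in (selections or [])]
    return cropped, remapped, index_map


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Face normals are accumulated unnormalised (the cross product's length is
    twice the face area, which provides the weighting).  Vertices referenced
    by no face get a zero normal.
    """
    tri = mesh.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(normals, mesh.faces[:, k], fn)
    lengths = np.linalg.norm(normals, axis=1)
    nz = lengths > 0
    normals[nz] /= lengths[nz, None]
    return normals


def random_rigid(
    max_rotation_deg: float,
    max_translation_mm: float,
    rng: np.random.Generator,
    about: np.ndarray | None = None,
) -> RigidTransform:
    """Seeded random rigid motion with bounded rotation angle and translation.

    The rotation axis is uniform on the sphere; the angle and translation
    magnitudes are uniform in [0, max].  With ``about`` given, the rotation
    pivots around that point so the motion stays local to the object.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(0.0, max_translation_mm) * direction
    if about is not None:
        c = np.asarray(about, dtype=np.float64).reshape(3)
        t = t + c - rot @ c
    return RigidTransform(rot, t)
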