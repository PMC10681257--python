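"""Mesh, selection and plane I/O.

Reading and writing of STL/PLY/OBJ goes through :mod:`trimesh`, always with
processing disabled: vertex order is the correspondence currency of the
whole method, so welding, re-indexing or sorting on load would silently
destroy it.  PLY is the colour-bearing dialect (per-vertex float ``quality``
plus 8-bit RGB); STL and OBJ cannot carry per-vertex scalars and drop them
with a warning.  Selections and planes live in JSON sidecar files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .mesh import MeshError, TriangleMesh, VertexSelection

__all__ = [
    "PlaneRecord",
    "SelectionFile",
    "load_mesh",
    "save_mesh",
    "load_selections",
    "save_selections",
    "load_plane",
    "save_plane",
    "DEFAULT_COLOUR_SCALE",
]

log = logging.getLogger(__name__)

# diverging colour scale endpoints (mm); asymmetries of interest are ~2 mm
DEFAULT_COLOUR_SCALE = (-2.0, 2.0)

_FORMATS = ("stl", "ply", "obj")


@dataclass(frozen=True)
class PlaneRecord:
    """Plane n·x = d with unit normal (mm)."""

    normal: np.ndarray
    offset: float
    note: str = ""

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise MeshError("plane normal must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            warnings.warn("plane normal was not unit length; re-normalised")
            object.__setattr__(self, "offset", float(self.offset) / norm)
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.normal - self.offset


@dataclass
class SelectionFile:
    """Sidecar document: named vertex-index selections for one mesh file."""

    mesh_name: str
    selections: list[VertexSelection] = field(default_factory=list)


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt and fmt != "auto":
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshError(f"unknown mesh format {fmt!r} (expected one of {_FORMATS})")
    return fmt


def load_mesh(path: str | Path, fmt: str | None = "auto") -> TriangleMesh:
    """Load a surface mesh preserving vertex order exactly as stored.

    Duplicate-vertex welding is off: STL triangle soups load with three
    vertices per face.  Polygonal OBJ faces are fan-triangulated by the
    reader, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    fmt = _resolve_format(path, fmt)
    loaded = trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshError(f"no geometry in {path}")
        loaded = geoms[0]
    faces = np.asarray(loaded.faces)
    if faces.size == 0 or len(loaded.vertices) == 0:
        raise MeshError(f"empty mesh in {path}")
    if faces.shape[1] != 3:  # pragma: no cover - trimesh triangulates on load
        log.warning("non-triangular faces in %s were triangulated", path)
    return TriangleMesh(np.asarray(loaded.vertices, dtype=np.float64), faces)


def _colourize_for_export(scalars, scale, palette):
    from .asymmetry import colourize  # local import to avoid cycle

    return colourize(scalars, scale=scale, palette=palette)


def save_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    fmt: str | None = "auto",
    vertex_scalars: np.ndarray | None = None,
    colour_scale: tuple[float, float] = DEFAULT_COLOUR_SCALE,
    palette: str = "coolwarm",
    encoding: str = "binary",
) -> Path:
    """Write a mesh; PLY additionally carries per-vertex scalars.

    ``vertex_scalars`` (mm) are stored as the PLY float ``quality``
    property and, mapped through the diverging ``palette`` over
    ``colour_scale``, as 8-bit RGB vertex colours.  STL/OBJ silently drop
    scalars (a warning is logged).
    """
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if vertex_scalars is not None:
        vertex_scalars = np.asarray(vertex_scalars, dtype=np.float64).ravel()
        if len(vertex_scalars) != mesh.n_vertices:
            raise MeshError(
                f"scalars length {len(vertex_scalars)} != "
                f"{mesh.n_vertices} vertices"
            )
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if vertex_scalars is not None:
        if fmt == "ply":
            tm.vertex_attributes["quality"] = vertex_scalars.astype(np.float32)
            tm.visual.vertex_colors = _colourize_for_export(
                vertex_scalars, colour_scale, palette
            )
        else:
            log.warning("%s cannot store per-vertex scalars; dropped", fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        tm.export(str(path), file_type="ply", encoding=encoding)
    else:
        tm.export(str(path), file_type=fmt)
    return path


def load_vertex_quality(path: str | Path) -> np.ndarray | None:
    """Read back the per-vertex ``quality`` property of a PLY file, if any."""
    loaded = trimesh.load(str(path), file_type="ply", process=False, maintain_order=True)
    raw = loaded.metadata.get("_ply_raw", {})
    vertex = raw.get("vertex", {})
    data = vertex.get("data")
    if data is None:
        return None
    try:
        q = data["quality"]
    except (KeyError, ValueError):
        return None
    return np.asarray(q, dtype=np.float64).ravel()


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def save_selections(doc: SelectionFile, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "mesh": doc.mesh_name,
        "selections": [
            {"name": s.name, "indices": s.indices.tolist()} for s in doc.selections
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_selections(
    path: str | Path, mesh: TriangleMesh | None = None
) -> SelectionFile:
    """Load a selection sidecar; with ``mesh`` given, bounds are enforced."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        mesh_name = payload["mesh"]
        items = payload["selections"]
    except (OSError, json.JSONDecodeError, KeyError, TypeError) as exc:
        raise MeshError(f"malformed selection file {path}: {exc}") from exc
    doc = SelectionFile(
        mesh_name=mesh_name,
        selections=[
            VertexSelection(name=i["name"], indices=np.asarray(i["indices"]),
                            mesh_id=mesh_name)
            for i in items
        ],
    )
    if mesh is not None:
        for sel in doc.selections:
            sel.validate_for(mesh)
    return doc


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------


def save_plane(plane: PlaneRecord, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "normal": plane.normal.tolist(),
                "offset": plane.offset,
                "note": plane.note,
            },
            indent=1,
        )
    )
    return path


def load_plane(path: str | Path) -> PlaneRecord:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return PlaneRecord(
            normal=np.asarray(payload["normal"], dtype=np.float64),
            offset=float(payload["offset"]),
            note=str(payload.get("note", "")),
        )
    except (OSError, json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise MeshError(f"malformed plane file {path}: {exc}") from exc
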