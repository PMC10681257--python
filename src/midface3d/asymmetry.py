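"""Distance maps and MAD statistics between original and mirrored surfaces.

Asymmetry is read off the superimposed pair as a directed distance map:
from each vertex of the original mesh to its exact closest point on the
aligned mirrored surface.  The sign follows the original's outward vertex
normal (positive where the mirrored surface lies outside).  Area summaries
use the MAD — mean absolute distance — over a vertex selection; comparing
MAD over a right-side area with its contralateral (index-identical on the
mirrored copy) area is the method's bilateral validity check: a perfect
superimposition makes the difference zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_COLOUR_SCALE
from .mesh import MeshError, TriangleMesh, VertexSelection, vertex_normals
from .register import SurfaceIndex

__all__ = [
    "DistanceMap",
    "AreaStats",
    "distance_map",
    "area_mad",
    "bilateral_difference",
    "colourize",
]


@dataclass(frozen=True)
class DistanceMap:
    """Per-vertex closest-point distances original -> mirrored surface."""

    distances: np.ndarray  # absolute, mm
    signed: np.ndarray  # sign via the source outward normal
    on_boundary: np.ndarray  # closest point lies on the target boundary

    def __post_init__(self) -> None:
        if not ((self.distances >= 0).all() and
                np.allclose(np.abs(self.signed), self.distances)):
            raise MeshError("inconsistent signed/absolute distances")


@dataclass(frozen=True)
class AreaStats:
    """MAD summary of a distance map over one measurement area."""

    name: str
    n_used: int
    mad: float
    max: float
    boundary_excluded_fraction: float


def distance_map(
    original: TriangleMesh,
    aligned_mirrored: TriangleMesh,
    target_index: SurfaceIndex | None = None,
) -> DistanceMap:
    """Exact directed distance map from ``original`` vertices to the
    ``aligned_mirrored`` surface."""
    index = target_index if target_index is not None else SurfaceIndex(aligned_mirrored)
    dist, closest, _faces, boundary = index.query(original.vertices)
    normals = vertex_normals(original)
    side = np.einsum("ij,ij->i", closest - original.vertices, normals)
    sign = np.where(side < 0, -1.0, 1.0)  # distance 0 counts as +
    return DistanceMap(distances=dist, signed=sign * dist, on_boundary=boundary)


def area_mad(
    dmap: DistanceMap,
    selection: VertexSelection,
    exclude_boundary: bool = True,
) -> AreaStats:
    """MAD of a distance map over a selection.

    Vertices whose closest point fell on the mirrored-mesh boundary are
    excluded by default: their distances measure the crop border, not
    asymmetry (the same logic as ICP overhang exclusion).
    """
    idx = selection.indices
    if idx.size == 0:
        raise MeshError(f"selection {selection.name!r} is empty")
    if idx[-1] >= len(dmap.distances):
        raise MeshError(
            f"selection {selection.name!r} exceeds the distance map length"
        )
    keep = ~dmap.on_boundary[idx] if exclude_boundary else np.ones(len(idx), bool)
    if not keep.any():
        raise MeshError(
            f"selection {selection.name!r} empty after boundary exclusion"
        )
    d = dmap.distances[idx[keep]]
    return AreaStats(
        name=selection.name,
        n_used=int(keep.sum()),
        mad=float(d.mean()),
        max=float(d.max()),
        boundary_excluded_fraction=float(1.0 - keep.mean()),
    )


def bilateral_difference(
    dmap: DistanceMap,
    area_right: VertexSelection,
    area_left: VertexSelection,
    exclude_boundary: bool = True,
) -> float:
    """MAD(right) − MAD(left): the headline bilateral validity statistic.

    Should be ~0 whenever the mirrored copy is well superimposed, because
    the two areas sample the same anatomy from the two sides.
    """
    right = area_mad(dmap, area_right, exclude_boundary)
    left = area_mad(dmap, area_left, exclude_boundary)
    return right.mad - left.mad


def colourize(
    values: np.ndarray | DistanceMap,
    scale: tuple[float, float] = DEFAULT_COLOUR_SCALE,
    palette: str = "coolwarm",
) -> np.ndarray:
    """Map signed distances to RGBA uint8 through a diverging palette.

    Values are clamped to ``scale`` (mm); the palette midpoint corresponds
    to zero distance when the scale is symmetric.
    """
    import matplotlib

    if isinstance(values, DistanceMap):
        values = values.signed
    lo, hi = scale
    if not lo < hi:
        raise MeshError("colour scale must satisfy min < max")
    v = np.clip(np.asarray(values, dtype=np.float64), lo, hi)
    cmap = matplotlib.colormaps[palette]
    rgba = cmap((v - lo) / (hi - lo))
    return (rgba * 255).round().astype(np.uint8)
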