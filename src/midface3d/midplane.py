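"""Midsagittal plane construction from contralateral vertex midpoints.

For any shape and an improper-isometry image of it (its aligned mirrored
duplicate), the midpoints of the segments joining index-corresponding
vertices are exactly coplanar — this holds for *any* relative orientation
of the two copies, not only after a good fit.  The common plane is the
mirror of the pair; when the mirrored copy has been best-fit onto the
original it is the midsagittal plane.  The plane is recovered by PCA of
the midpoint cloud: its normal is the eigenvector of the covariance with
the smallest eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PlaneRecord
from .mesh import CanonicalFrame, MeshError, TriangleMesh
from .register import ICPConfig, ICPResult, mirror_fit

__all__ = [
    "DegeneratePlaneError",
    "PlaneFitStats",
    "PlaneDifference",
    "midpoints",
    "fit_midsagittal_plane",
    "plane_difference",
    "midsagittal_from_mesh",
]

# cloud is usable when the in-plane spread dwarfs the out-of-plane spread
_DEGENERACY_RATIO = 1e3


class DegeneratePlaneError(RuntimeError):
    """Midpoint cloud too collapsed (near-collinear/point) to define a plane."""


@dataclass(frozen=True)
class PlaneFitStats:
    """Residual diagnostics of a PCA plane fit (mm)."""

    max_residual: float
    rms_residual: float


@dataclass(frozen=True)
class PlaneDifference:
    """Difference between two midsagittal planes in clinical terms.

    z_mm
        Lateral displacement along the mean normal, measured at the
        reference point (positive toward the subject's left).
    xrot_deg
        Signed angle about the anteroposterior axis (normal projections
        onto the frame YZ plane).
    yrot_deg
        Signed angle about the vertical axis (projections onto XZ).
    """

    z_mm: float
    xrot_deg: float
    yrot_deg: float

    def max_abs(self) -> float:
        return max(abs(self.z_mm), abs(self.xrot_deg), abs(self.yrot_deg))


def midpoints(original: TriangleMesh, aligned_mirrored: TriangleMesh) -> np.ndarray:
    """Per-index midpoints (v_i + v'_i) / 2 between the two copies."""
    if original.n_vertices != aligned_mirrored.n_vertices:
        raise MeshError(
            "vertex count mismatch: "
            f"{original.n_vertices} vs {aligned_mirrored.n_vertices}"
        )
    return 0.5 * (original.vertices + aligned_mirrored.vertices)


def fit_midsagittal_plane(
    cloud: np.ndarray, frame: CanonicalFrame | None = None
) -> tuple[PlaneRecord, PlaneFitStats, np.ndarray]:
    """PCA plane through a midpoint cloud.

    The plane passes through the cloud centroid; its normal is the
    smallest-eigenvalue eigenvector of the coordinate covariance, with its
    sign oriented toward the frame's +Z (subject's left) so signed offsets
    are comparable across runs.

    Returns the plane, residual statistics over the cloud, and the
    eigenvalue triple in descending order.  Raises
    :class:`DegeneratePlaneError` when the second-largest to smallest
    eigenvalue ratio falls below 1e3 — the cloud is then close to a line or
    point (the net improper isometry approaches a rotary reflection) and no
    meaningful plane exists.
    """
    pts = np.asarray(cloud, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise MeshError("need at least 3 midpoints")
    frame = frame or CanonicalFrame()
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_desc = evals[::-1].copy()
    # degenerate when the in-plane spread does not dominate the out-of-plane
    # spread (near-collinear), or has collapsed entirely (near-point)
    if (
        lam_desc[1] < _DEGENERACY_RATIO * lam_desc[2]
        or lam_desc[1] <= 1e-12 * max(lam_desc[0], 1.0)
    ):
        raise DegeneratePlaneError(
            "degenerate midpoint cloud: eigenvalues "
            f"{lam_desc.tolist()} (ratio below {_DEGENERACY_RATIO:g})"
        )
    normal = evecs[:, 0]
    if np.dot(normal, frame.z) < 0:
        normal = -normal
    residuals = centred @ normal
    plane = PlaneRecord(
        normal=normal,
        offset=float(np.dot(normal, centroid)),
        note="PCA fit of contralateral vertex midpoints",
    )
    stats = PlaneFitStats(
        max_residual=float(np.abs(residuals).max()),
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
    )
    return plane, stats, lam_desc


def _signed_angle(a2: np.ndarray, b2: np.ndarray) -> float:
    """Signed angle (degrees) from 2-vector a2 to b2."""
    cross = a2[0] * b2[1] - a2[1] * b2[0]
    dot = float(a2 @ b2)
    return float(np.degrees(np.arctan2(cross, dot)))


def plane_difference(
    a: PlaneRecord,
    b: PlaneRecord,
    frame: CanonicalFrame | None = None,
    reference_point: np.ndarray | None = None,
) -> PlaneDifference:
    """Lateral shift and rotations needed to carry plane ``a`` onto ``b``.

    ``reference_point`` anchors the lateral (Z) measurement; it is first
    projected onto plane ``a`` and the signed distance to plane ``b`` is
    then taken along the mean of the two normals.  Pass the original mesh
    centroid for reproducibility comparisons.
    """
    frame = frame or CanonicalFrame()
    na, nb = a.normal, b.normal
    for n in (na, nb):
        if np.dot(n, frame.z) < np.cos(np.deg2rad(45.0)):
            raise MeshError(
                "plane normal more than 45 degrees from the lateral axis; "
                "orientation contract broken"
            )
    # rotation about the anteroposterior (X) axis: projections onto YZ
    xrot = _signed_angle(
        np.array([np.dot(na, frame.y), np.dot(na, frame.z)]),
        np.array([np.dot(nb, frame.y), np.dot(nb, frame.z)]),
    )
    # rotation about the vertical (Y) axis: projections onto XZ
    yrot = _signed_angle(
        np.array([np.dot(na, frame.x), np.dot(na, frame.z)]),
        np.array([np.dot(nb, frame.x), np.dot(nb, frame.z)]),
    )
    ref = (
        np.zeros(3)
        if reference_point is None
        else np.asarray(reference_point, dtype=np.float64).reshape(3)
    )
    on_a = ref - (np.dot(na, ref) - a.offset) * na
    mean_n = na + nb
    mean_n = mean_n / np.linalg.norm(mean_n)
    denom = float(np.dot(nb, mean_n))
    z = (b.offset - float(np.dot(nb, on_a))) / denom
    return PlaneDifference(z_mm=float(z), xrot_deg=xrot, yrot_deg=yrot)


def midsagittal_from_mesh(
    original: TriangleMesh,
    frame: CanonicalFrame | None = None,
    selections=None,
    config: ICPConfig | None = None,
) -> tuple[PlaneRecord, ICPResult, TriangleMesh, PlaneFitStats]:
    """Full pipeline: mirror, best-fit, midpoints, PCA plane.

    Convenience composition of :func:`midface3d.register.mirror_fit`,
    :func:`midpoints` and :func:`fit_midsagittal_plane`.
    """
    frame = frame or CanonicalFrame()
    aligned, _net, icp_result = mirror_fit(original, frame, selections, config)
    cloud = midpoints(original, aligned)
    plane, stats, _ = fit_midsagittal_plane(cloud, frame)
    return plane, icp_result, aligned, stats
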