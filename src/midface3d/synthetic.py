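"""Synthetic face-like surfaces with known, constructed symmetry.

No stereophotogrammetric face scans ship with this package, so validation
runs on generated surfaces: a smooth heightfield x = f(y, z) over a regular
(y, z) grid, built from Gaussian features applied in mirrored pairs so the
base surface satisfies f(y, z) = f(y, −z) *exactly* (to the last bit).
The ground-truth midsagittal plane is therefore z = 0 before any pose is
applied, and every grid vertex has an explicit contralateral partner.

On top of the symmetric base the generator injects controlled asymmetries
(one-sided Gaussian bumps, smooth correlated random fields), rigid pose
perturbations, and four cropping variants mimicking progressively reduced
facial surface extents — full face, bilateral posterior crop, unilateral
posterior crop, and small random peripheral crops by a simulated operator.

Everything is deterministic given the seeds carried in the specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import PlaneRecord
from .mesh import (
    CanonicalFrame,
    MeshError,
    RigidTransform,
    TriangleMesh,
    VertexSelection,
    crop_mask,
    random_rigid,
)

__all__ = [
    "GaussianFeature",
    "FaceSpec",
    "AsymmetrySpec",
    "GroundTruth",
    "CropVariant",
    "generate_face",
    "inject_asymmetry",
    "apply_pose",
    "make_crops",
    "measurement_areas",
    "default_features",
]

# footprint = vertices displaced by more than this fraction of the amplitude
_FOOTPRINT_FRACTION = 0.05


@dataclass(frozen=True)
class GaussianFeature:
    """Isotropic Gaussian height feature: amplitude * exp(-r^2 / 2 width^2).

    For symmetric base features ``z`` is a magnitude: features with z > 0
    are applied at both +z and −z; z == 0 places a single midline feature.
    For asymmetry bumps ``z`` is a signed position and is applied once.
    """

    y: float
    z: float
    amplitude: float  # mm, negative for troughs
    width: float  # mm (Gaussian sigma)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise MeshError("feature width must be positive")


def default_features() -> list[GaussianFeature]:
    """A coarse face: dome, nose, brow ridges, cheeks, eye sockets, mouth,
    chin.  Centres in mm on the 160 (vertical) x 140 (lateral) sheet."""
    return [
        GaussianFeature(y=0.0, z=0.0, amplitude=40.0, width=65.0),  # facial dome
        GaussianFeature(y=5.0, z=0.0, amplitude=14.0, width=10.0),  # nose
        GaussianFeature(y=30.0, z=22.0, amplitude=5.0, width=12.0),  # brow ridges
        GaussianFeature(y=-5.0, z=38.0, amplitude=7.0, width=18.0),  # cheeks
        GaussianFeature(y=22.0, z=18.0, amplitude=-3.0, width=8.0),  # eye sockets
        GaussianFeature(y=-35.0, z=0.0, amplitude=-4.0, width=10.0),  # mouth
        GaussianFeature(y=-62.0, z=0.0, amplitude=8.0, width=13.0),  # chin
    ]


@dataclass(frozen=True)
class FaceSpec:
    """Parameters of the symmetric base surface.

    The default extents (160 mm vertical x 140 mm lateral) and ~2 mm grid
    pitch are in the range of adult facial surface scans after cropping.
    ``noise_sd`` adds Gaussian surface roughness drawn once per ±z pair so
    the base stays exactly symmetric.
    """

    ny: int = 80
    nz: int = 70
    height: float = 160.0
    width: float = 140.0
    features: tuple[GaussianFeature, ...] = field(
        default_factory=lambda: tuple(default_features())
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ny < 8 or self.nz < 8:
            raise MeshError("grid resolution must be at least 8x8")
        if self.height <= 0 or self.width <= 0 or self.noise_sd < 0:
            raise MeshError("invalid face spec")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Vertical and lateral coordinates; the lateral axis is exactly
        antisymmetric about 0."""
        ys = (np.arange(self.ny) - (self.ny - 1) / 2.0) * (
            self.height / (self.ny - 1)
        )
        zs = (np.arange(self.nz) - (self.nz - 1) / 2.0) * (
            self.width / (self.nz - 1)
        )
        return ys, zs


@dataclass(frozen=True)
class AsymmetrySpec:
    """One-sided perturbations breaking the constructed symmetry.

    ``bumps`` are Gaussian features with *signed* lateral centres (negative
    z = subject's right).  The optional random field is white noise
    smoothed to ``field_correlation_mm`` and scaled so its maximum absolute
    displacement equals ``field_amplitude_mm``.
    """

    bumps: tuple[GaussianFeature, ...] = ()
    field_amplitude_mm: float = 0.0
    field_correlation_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_amplitude_mm < 0 or self.field_correlation_mm <= 0:
            raise MeshError("invalid asymmetry spec")


@dataclass(frozen=True)
class GroundTruth:
    """What is known by construction about a generated face."""

    plane: PlaneRecord  # true symmetry plane in current (posed) coordinates
    pose: RigidTransform  # net pose applied since generation
    partner: np.ndarray  # index of each vertex's contralateral grid partner
    grid_y: np.ndarray  # unposed vertical coordinates of the grid rows
    grid_z: np.ndarray  # unposed lateral coordinates of the grid columns
    footprints: dict[str, VertexSelection] = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return len(self.grid_y), len(self.grid_z)

    def vertex_yz(self) -> tuple[np.ndarray, np.ndarray]:
        """Unposed (y, z) of every vertex, in grid order."""
        yy, zz = np.meshgrid(self.grid_y, self.grid_z, indexing="ij")
        return yy.ravel(), zz.ravel()


@dataclass(frozen=True)
class CropVariant:
    """One cropped duplicate of a face, with selections carried along."""

    name: str
    mesh: TriangleMesh
    selections: list[VertexSelection]
    index_map: np.ndarray


def _feature_height(ys: np.ndarray, zs: np.ndarray,
                    feat: GaussianFeature, mirrored: bool) -> np.ndarray:
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    def g(zc):
        r2 = (yy - feat.y) ** 2 + (zz - zc) ** 2
        return feat.amplitude * np.exp(-r2 / (2.0 * feat.width**2))
    if mirrored and feat.z != 0.0:
        return g(feat.z) + g(-feat.z)
    return g(feat.z)


def generate_face(spec: FaceSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Build the symmetric heightfield face.

    The grid is triangulated two triangles per cell with a fixed diagonal
    and winding chosen so outward normals point along +X (anterior).  With
    ``noise_sd = 0`` every vertex (x, y, z) has an exact counterpart at
    (x, y, −z); noise preserves this because the draw for a ±z pair is
    shared.
    """
    ys, zs = spec.grid()
    x = np.zeros((spec.ny, spec.nz))
    for feat in spec.features:
        x += _feature_height(ys, zs, feat, mirrored=True)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        half = rng.normal(0.0, spec.noise_sd, size=(spec.ny, (spec.nz + 1) // 2))
        noise = np.empty((spec.ny, spec.nz))
        noise[:, : half.shape[1]] = half
        noise[:, spec.nz - half.shape[1]:] = half[:, ::-1]
        x += noise
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    vertices = np.column_stack([x.ravel(), yy.ravel(), zz.ravel()])

    idx = np.arange(spec.ny * spec.nz).reshape(spec.ny, spec.nz)
    v00 = idx[:-1, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v10 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    mesh = TriangleMesh(vertices, faces)

    partner = idx[:, ::-1].ravel()  # (i, j) <-> (i, nz-1-j)
    truth = GroundTruth(
        plane=PlaneRecord(normal=np.array([0.0, 0.0, 1.0]), offset=0.0,
                          note="constructed symmetry plane"),
        pose=RigidTransform.identity(),
        partner=partner,
        grid_y=ys,
        grid_z=zs,
    )
    return mesh, truth


def inject_asymmetry(
    mesh: TriangleMesh, truth: GroundTruth, aspec: AsymmetrySpec
) -> tuple[TriangleMesh, GroundTruth]:
    """Add one-sided height displacements to an *unposed* face.

    Displacements act along the surface-height axis (+X).  Each bump's
    footprint (vertices displaced by more than 5% of its amplitude) and the
    footprint's mirrored twin are recorded as ground-truth selections named
    ``bump<i>`` and ``bump<i>_twin``.
    """
    if not np.allclose(truth.pose.rotation, np.eye(3)) or np.any(
        truth.pose.translation
    ):
        raise MeshError("inject asymmetry before applying a pose")
    y, z = truth.vertex_yz()
    delta = np.zeros(mesh.n_vertices)
    footprints = dict(truth.footprints)
    for i, bump in enumerate(aspec.bumps):
        r2 = (y - bump.y) ** 2 + (z - bump.z) ** 2
        d = bump.amplitude * np.exp(-r2 / (2.0 * bump.width**2))
        delta += d
        foot = np.flatnonzero(
            np.abs(d) > _FOOTPRINT_FRACTION * abs(bump.amplitude)
        )
        footprints[f"bump{i}"] = VertexSelection(f"bump{i}", foot)
        footprints[f"bump{i}_twin"] = VertexSelection(
            f"bump{i}_twin", truth.partner[foot]
        )
    if aspec.field_amplitude_mm > 0:
        ny, nz = truth.grid_shape
        dy = truth.grid_y[1] - truth.grid_y[0]
        dz = truth.grid_z[1] - truth.grid_z[0]
        rng = np.random.default_rng(aspec.seed)
        white = rng.normal(size=(ny, nz))
        smooth = gaussian_filter(
            white, sigma=(aspec.field_correlation_mm / dy,
                          aspec.field_correlation_mm / dz)
        )
        peak = np.abs(smooth).max()
        if peak > 0:
            delta += (aspec.field_amplitude_mm / peak) * smooth.ravel()
    vertices = mesh.vertices.copy()
    vertices[:, 0] += delta
    return TriangleMesh(vertices, mesh.faces), replace(truth, footprints=footprints)


def apply_pose(
    mesh: TriangleMesh,
    truth: GroundTruth,
    rotation_deg: float,
    translation_mm: float,
    seed: int,
) -> tuple[TriangleMesh, GroundTruth]:
    """Rigidly move the face by a seeded random pose (rotation about the
    centroid); the ground-truth plane transforms covariantly."""
    if rotation_deg < 0 or rotation_deg > 30 or translation_mm < 0:
        raise MeshError("pose must have 0 <= rotation <= 30 deg and "
                        "non-negative translation")
    rng = np.random.default_rng(seed)
    motion = random_rigid(rotation_deg, translation_mm, rng, about=mesh.centroid())
    posed = TriangleMesh(motion.apply(mesh.vertices), mesh.faces)
    n_new = motion.rotation @ truth.plane.normal
    d_new = truth.plane.offset + float(n_new @ motion.translation)
    return posed, replace(
        truth,
        plane=PlaneRecord(n_new, d_new, note=truth.plane.note),
        pose=motion.compose(truth.pose),
    )


# ---------------------------------------------------------------------------
# measurement areas and crops
# ---------------------------------------------------------------------------

# rectangles in unposed (y, z) mm; subject-right is negative z
AREA_A_Y = (-35.0, 30.0)
AREA_A_Z = (-18.0, 18.0)
AREA_B_Y = (0.0, 28.0)
AREA_B_Z = (-45.0, -12.0)


def _rect_indices(y, z, y_range, z_range) -> np.ndarray:
    return np.flatnonzero(
        (y >= y_range[0]) & (y <= y_range[1]) & (z >= z_range[0]) & (z <= z_range[1])
    )


def measurement_areas(truth: GroundTruth) -> list[VertexSelection]:
    """The midface Area A and bilateral Area B selections.

    Area A straddles the midline (brow-to-mouth band); Area B sits on the
    subject's right infraorbital region, and Area B left is its exact
    contralateral twin through the grid partner map, so the two have equal
    cardinality by construction.
    """
    y, z = truth.vertex_yz()
    a = _rect_indices(y, z, AREA_A_Y, AREA_A_Z)
    b_right = _rect_indices(y, z, AREA_B_Y, AREA_B_Z)
    return [
        VertexSelection("area_A", a),
        VertexSelection("area_B_right", b_right),
        VertexSelection("area_B_left", truth.partner[b_right]),
    ]


def make_crops(
    mesh: TriangleMesh,
    frame: CanonicalFrame,
    truth: GroundTruth,
    selections: list[VertexSelection] | None = None,
    nibble_seed: int = 0,
) -> dict[str, CropVariant]:
    """Four cropping variants of decreasing / perturbed extent.

    crop1
        Near-full face (slight peripheral trim), the reference extent.
    crop2
        Bilateral posterior crop: lateral extent reduced symmetrically.
    crop3
        Unilateral: subject-right side cropped as crop2, left as crop1 —
        lateral extent asymmetric about the true plane.
    crop4
        crop1 minus a few seeded random peripheral box nibbles (< 5% of
        vertices), emulating slightly different freeform operator crops;
        vary ``nibble_seed`` to emulate different operators.

    Lateral containment crop1 ⊇ crop3 ⊇ crop2 holds by construction.  The
    mesh must be in its unposed frame.
    """
    if selections is None:
        selections = measurement_areas(truth)
    y, z = truth.vertex_yz()
    hw = float(truth.grid_z[-1])  # lateral half-extent
    hh = float(truth.grid_y[-1])
    full_z = 0.95 * hw
    tight_z = 0.64 * hw
    y_lim = 0.95 * hh

    def band(z_lo, z_hi):
        return (z >= z_lo) & (z <= z_hi) & (y >= -y_lim) & (y <= y_lim)

    masks = {
        "crop1": band(-full_z, full_z),
        "crop2": band(-tight_z, tight_z),
        "crop3": band(-tight_z, full_z),
    }
    # crop4: peripheral nibbles out of the crop1 extent
    rng = np.random.default_rng(nibble_seed)
    mask4 = masks["crop1"].copy()
    for _ in range(4):
        side = rng.integers(0, 4)
        size = rng.uniform(8.0, 14.0)
        if side in (0, 1):  # left/right lateral borders
            zc = full_z if side == 0 else -full_z
            yc = rng.uniform(-y_lim, y_lim)
        else:  # top/bottom borders
            yc = y_lim if side == 2 else -y_lim
            zc = rng.uniform(-full_z, full_z)
        in_nibble = (np.abs(y - yc) <= size) & (np.abs(z - zc) <= size)
        mask4 &= ~in_nibble
    masks["crop4"] = mask4

    out: dict[str, CropVariant] = {}
    for name, mask in masks.items():
        cropped, sels, index_map = crop_mask(mesh, mask, selections)
        out[name] = CropVariant(name, cropped, sels, index_map)
    return out
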