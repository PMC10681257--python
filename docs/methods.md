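# Methods

## The model

The package treats facial asymmetry as a purely geometric question about a
triangle surface mesh S ⊂ ℝ³ (millimetres). Let F be an improper isometry
(orthonormal linear part M with det M = −1, translation t). The mirrored
duplicate S′ = F(S) inherits the vertex array of S, so vertex i of S′ is
the contralateral image of vertex i of S. After S′ is rigidly best-fit
onto S, three quantities are read off:

* the **midsagittal plane**, fitted to the midpoints mᵢ = (vᵢ + v′ᵢ)/2;
* the **distance map** dᵢ = min over the S′ surface of ‖vᵢ − x‖, signed
  along the outward vertex normal of S;
* per-area **MAD** statistics, mean |dᵢ| over a named vertex selection.

**Coplanarity.** For any improper isometry, the map v ↦ (v + F v)/2 has
linear part (I + M)/2. Since M is orthonormal with det −1, it has
eigenvalue −1; the corresponding eigenvector n is annihilated by (I+M)/2,
so every midpoint lies in a plane orthogonal to n (unless M is a rotary
reflection with a ±180° rotary component, in which case (I+M)/2 drops to
rank ≤ 1 and the midpoints collapse to a line or point). The midpoint
plane therefore exists *exactly*, independent of how well the two copies
are aligned — alignment quality only decides whether that plane is
anatomically meaningful. The test suite verifies the residual at machine
precision (≤ 1e−9 × bounding-box diagonal) for random improper isometries
with rotation up to 30°.

**Conventions.** Right-handed frame, X+ anterior, Y+ superior, Z+ toward
the subject's left; lengths in mm, angles in degrees. The mirror plane is
the plane through the mesh centroid with normal Z — the choice is
immaterial because any other mirror differs by a rigid motion that the
subsequent ICP absorbs. Face winding is reversed on reflection so outward
normals stay outward.

## Registration

ICP aligns the mirrored (moving) mesh onto the original (fixed) mesh,
which never moves. Defaults are the full-strength configuration:
point-to-plane metric, exact nearest neighbours, 100% overlap, 100%
sampling, overhang exclusion on. Each iteration:

1. **Exact correspondences.** Every moving vertex is paired with its
   exact closest point on the fixed surface. The search uses a k-d tree
   over triangle centroids purely for *pruning*: the nearest centroid's
   triangle gives an upper bound U on the true distance, and only
   triangles whose centroid lies within U + r_max (r_max = largest
   centroid-to-corner radius) can beat it, so scanning that ball preserves
   exactness. Point-to-triangle minimisation is the standard
   closest-feature region decomposition, vectorised; ties between faces
   break toward the smaller face index for determinism.
2. **Overhang exclusion.** A correspondence is dropped when its closest
   point lies on a boundary edge or boundary vertex of the target (an edge
   with exactly one incident face). This prevents border drag when the two
   copies have different extents (unilateral crops). The region code of
   the closest-point computation identifies edge/vertex contacts directly,
   with no distance threshold beyond 1e−9 mm arithmetic.
3. **Update.** The linearised point-to-plane least squares (residual
   (Rp + t − q)·n, small-angle parameterisation) is solved as a 6×6
   normal system; the rotation is rebuilt exactly from the axis–angle
   vector each iteration, so the accumulated transform is always a proper
   rigid motion. With the point-to-point metric a Kabsch fit is used
   instead.
4. **Convergence** when the RMS residual changes by less than 1e−6 mm
   (default), capped at 200 iterations. Residual change rather than
   transform change is monitored because the asymmetry of the subject
   puts a nonzero floor under the residual itself; near the optimum the
   Gauss–Newton step is quadratically convergent, so the pose error at
   stop is far below the 0.01 mm scale of interest.

The point-to-plane normal is the target triangle's face normal at the
closest point, not an interpolated vertex normal: exact,
orientation-consistent, and indistinguishable from interpolation at the
mesh densities involved. Sub-sampling, if requested, is a seeded uniform
vertex draw made once per run.

## Plane fitting and plane differences

The plane is fit by PCA over **all** vertex midpoints (the theorem makes
three points sufficient; using all of them is the most accurate choice and
removes a free parameter). The normal is the smallest-eigenvalue
eigenvector of the covariance, sign-oriented toward +Z. A degeneracy
guard rejects clouds whose second-largest/smallest eigenvalue ratio falls
below 1e3 — the rotary-reflection collapse discussed above, which cannot
occur after a successful near-reflection fit.

Two planes are compared in clinical terms: Xrot is the signed angle
between the normals' projections onto the frame YZ plane (rotation about
the anteroposterior axis), Yrot the analogue in XZ (about the vertical
axis), and Z the signed distance between the planes along the mean normal,
measured at a reference point (the original mesh centroid projected onto
the first plane). The anchor point and axis decomposition are a
convention; other decompositions could differ at the 1e−3 level for large
rotations, which is irrelevant at the sub-0.1 differences the method
produces.

## Distance maps and MAD

Distances are directed, from original vertices to the mirrored surface,
reusing the exact closest-point machinery; both signed and absolute values
are kept, since a diverging colour map needs sign while MAD uses the
absolute value. Vertices whose closest point lands on the target boundary
are excluded from MAD by default — such distances measure the crop
border, not asymmetry. Colour maps default to ±2 mm endpoints (the
magnitude scale at which inter-crop differences become clinically
visible) through a diverging palette.

## The synthetic generator

Faces are heightfields x = f(y, z) on a regular grid (default 80 × 70
vertices over 160 mm × 140 mm, ≈ 2 mm pitch, in the density range of
cropped facial scans), built from Gaussian features (dome, nose, brow,
cheeks, orbit troughs, mouth, chin) applied in mirrored ±z pairs. Because
the lateral grid is exactly antisymmetric and the feature sums commute,
f(y, z) = f(y, −z) holds bit-exactly, the true symmetry plane is z = 0,
and every vertex has an explicit contralateral partner index. Measurement
areas mimic the classic layout: a midline brow-to-mouth rectangle (Area
A) and a right infraorbital rectangle (Area B) whose left twin is the
partner image, guaranteeing equal cardinality.

Asymmetries are one-sided Gaussian bumps (with recorded footprints: the
vertices displaced by > 5% of the amplitude, plus their mirrored twins)
and/or a smooth random field (white noise Gaussian-filtered to a 20 mm
correlation length, scaled to a chosen maximum amplitude). Optional
surface noise shares its draw between ±z so it never breaks the ground
truth. Crop variants: crop1 trims 5% at the periphery (reference
extent); crop2 cuts the lateral extent to 64% bilaterally; crop3 does so
unilaterally (subject-right); crop4 removes four seeded random peripheral
box nibbles (< 5% of vertices) from crop1 — different nibble seeds play
the role of different operators performing a freeform crop. All
randomness sits behind explicit seeds.

What the generator does **not** emulate: scanner noise correlated with
curvature, holes and self-occlusions, hair and eye artefacts,
non-heightfield topology (ears, nostrils), and anatomically realistic
asymmetry patterns. Passing tests therefore demonstrate the geometric
correctness and stability of the *method*, not the clinical distribution
of asymmetries in any population.

## Validation experiments and problem sizes

The validation suite (tests and `scripts/acceptance.py`) uses the default
80 × 70 grid (5600 vertices):

* **Plane reproducibility** — 10 seeded faces with injected bumps; the
  aligned mirrored mesh is perturbed by random rigid motions ≤ 3° / 3 mm
  and re-superimposed, twice per face; the re-built plane differs from the
  reference by < 1e−3 mm/° in all components (bound checked: 0.1).
* **Superimposition reproducibility** — same runs; summed MAD over the
  three measurement areas between repeat and reference alignments is
  < 1e−3 mm (bound: 0.01 mm).
* **Bilateral validity** — 20 faces with 1 mm random asymmetry fields;
  |MAD(B right) − MAD(B left)| is ~0.02–0.04 mm at the 95th percentile
  (bound: 0.1 mm).
* **Crop repeatability** — crops 1–3 of 5 faces, perturbed and refit; max
  corresponding-vertex displacement < 1e−3 mm (bound: 0.05 mm).
* **Exactness** — indexed closest-point distances equal an independent
  brute-force all-triangle scan to 1e−9 mm.
* **Recovery** — the symmetric-fixture plane matches ground truth to
  < 0.01° / 0.01 mm, and ICP inverts known rigid displacements (≤ 8°,
  8 mm) to 1e−4 mm.

## Known limitations

* Distances are closest-point, not anatomically corresponding; the
  bilateral checks validate correspondence only statistically.
* The overhang rule (boundary closest points) is one reasonable reading of
  "exclude overhang regions"; other implementations may use distance or
  normal-angle thresholds and would differ near borders.
* Cropping keeps whole faces only (no re-meshing at the cut), so crop
  borders are ragged at the one-edge scale.
* Heightfield fixtures cannot probe behaviour on closed or multi-valued
  surfaces; the algorithms themselves do not assume heightfield topology,
  but that path is untested.
* Very large asymmetries (comparable to the feature scale) would drag the
  ICP optimum itself; the method measures asymmetry about the best
  compromise fit, as any mirror-based approach does.
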