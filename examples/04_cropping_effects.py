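"""Effect of facial surface extent (cropping) on the outcomes.

Four crop variants of the same asymmetric face are each superimposed with
their own mirrored duplicate: a near-full face (crop1), a tight bilateral
posterior crop (crop2), a unilateral crop (crop3), and crop1 minus small
random peripheral nibbles (crop4).  The midsagittal plane barely moves
across variants, while the measured area MAD shrinks with the tighter
crops — smaller surfaces are approximated better locally, so asymmetry
outcomes must always be interpreted relative to the surface extent used.
"""

import midface3d as mf

frame = mf.CanonicalFrame()
mesh, truth = mf.generate_face(mf.FaceSpec(seed=1))
mesh, truth = mf.inject_asymmetry(
    mesh,
    truth,
    mf.AsymmetrySpec(
        bumps=(mf.GaussianFeature(y=-5, z=-30, amplitude=1.0, width=10.0),),
        field_amplitude_mm=0.5,
        field_correlation_mm=20.0,
        seed=1,
    ),
)

crops = mf.make_crops(mesh, frame, truth)
planes, mads = {}, {}
for name, crop in crops.items():
    aligned, _, _ = mf.mirror_fit(crop.mesh, frame, crop.selections)
    planes[name], _, _ = mf.fit_midsagittal_plane(
        mf.midpoints(crop.mesh, aligned), frame
    )
    dmap = mf.distance_map(crop.mesh, aligned)
    mads[name] = {s.name: mf.area_mad(dmap, s).mad for s in crop.selections}

centroid = crops["crop1"].mesh.centroid()
print("plane difference vs crop1 (Z mm, Xrot deg, Yrot deg):")
for name in ("crop2", "crop3", "crop4"):
    d = mf.plane_difference(planes["crop1"], planes[name], frame, centroid)
    print(f"  {name}: {d.z_mm:+.3f}  {d.xrot_deg:+.3f}  {d.yrot_deg:+.3f}")

print("area MAD (mm) per crop:")
for name, m in mads.items():
    line = "  ".join(f"{k} {v:.3f}" for k, v in m.items())
    print(f"  {name}: {line}")
# plane differences stay well under 0.5 mm / 0.5 deg.  The extent effect
# is visible in area A (0.074 mm under crop1 vs 0.055 mm under crop2/3):
# a smaller surface lets ICP fit the remaining area more closely, so
# tighter crops report slightly smaller asymmetry on average
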