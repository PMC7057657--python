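"""Generate one labeled plant phantom and inspect its composition.

A phantom is a synthetic rosebush-like shoot: tubular trunk/branches/petioles
(stem class) carrying thin elliptical blades (leaf class), rasterized on a
0.5 mm voxel grid and exported both as a label volume and as the surface
point cloud every point-based method consumes.
"""

from shootseg import OrganLabel, PhantomSpec, generate_phantom

model = generate_phantom(PhantomSpec(seed=1))

nx, ny, nz = model.label_grid.shape
print(f"label grid : {nx} x {ny} x {nz} voxels at {model.label_grid.spacing} mm")
print(f"shoot      : {model.shoot_voxel_count} voxels")
print(f"leaf       : {model.class_fraction(OrganLabel.LEAF):.1%} of shoot voxels")
print(f"stem       : {model.class_fraction(OrganLabel.STEM):.1%} of shoot voxels")
print(f"surface    : {len(model.cloud)} points (one per surface voxel)")

# The leaf/stem split mirrors real X-ray CT rosebush models, where leaves are
# ~70-80% of shoot voxels and nearly all shoot voxels lie on the surface
# because blades are sub-millimetre thin.
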