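"""Sub-voxel localization of a 1-mm tantalum bead in a CT-like volume.

Rasterizes a bead at a deliberately awkward sub-voxel position (0.72-mm
pixels, 0.5-mm slices) and recovers its center from a rough operator seed.
"""

import numpy as np

import ctmigration as cm

true_center = np.array([10.25, 5.00, 7.75])  # mm, off every voxel center
spec = cm.PhantomSpec(bone_beads=true_center[None, :], ring_n_beads=0)
volume, truth = cm.rasterize_phantom(spec, seed=0)

seed_guess = true_center + np.array([0.3, -0.2, 0.2])  # operator click
detection = cm.refine_bead_center(volume, seed_guess, threshold=400.0)

err = np.linalg.norm(detection.center - true_center)
print(
    "volume            : "
    f"{volume.shape} voxels at {tuple(map(float, volume.spacing))} mm"
)
print(f"true center       : {true_center}")
print(f"recovered center  : {np.round(detection.center, 4)}")
print(f"error             : {err:.4f} mm ({detection.n_voxels} supra-threshold voxels)")
# The bead spans only ~2 voxels, yet the partial-volume-weighted centroid
# recovers its center to ~0.01 mm -- two orders of magnitude below the
# voxel size, which is what makes micro-motion measurement possible.
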