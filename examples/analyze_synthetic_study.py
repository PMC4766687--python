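"""Measure a known implant motion from a synthetic paired study.

Builds a phantom study in which the whole assembly is repositioned (as a
patient would lie differently in the scanner) and the cup is additionally
rotated 1.9 degrees about z and pushed 0.3 mm along x about its own marker
centroid.  The analysis must ignore the repositioning and report only the
implant motion.
"""

import numpy as np

import ctmigration as cm

spec = cm.PhantomSpec()  # 9 bone beads + 8-bead cup ring, 1-mm beads

reposition = cm.RigidTransform.from_euler((8.0, -5.0, 12.0), (25.0, -10.0, 15.0))
implant_motion = cm.implant_motion_about_centroid(
    spec, angles=(0.0, 0.0, 1.9), translation=(0.3, 0.0, 0.0)
)
pair, truth = cm.simulate_landmark_study(
    spec, reposition, implant_motion, noise_sd=0.05, seed=42
)

result = cm.analyze_study(pair)

np.set_printoptions(precision=3, suppress=True)
print("injected  (rx ry rz tx ty tz):", np.round(truth.expected_dof(), 3))
print("recovered (rx ry rz tx ty tz):", np.round(result.dof(), 3))
print(f"mean bone registration error : {result.bone_error.mean_error:.3f} mm")
print(f"mean prosthetic fit error    : {result.prosthetic_error.mean_error:.3f} mm")
print(f"bone condition number        : {result.bone_condition.condition_number:.2f}")
print(f"ring condition number (aug.) : {result.prosthetic_condition.condition_number:.2f}")
# The recovered six degrees of freedom match the injected motion to within
# the bead-localization noise; the 25-mm repositioning leaves no trace.
# Registration errors of ~0.05-0.1 mm mirror the landmark noise, and both
# condition numbers are small: the marker configurations determine the
# motion well.
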