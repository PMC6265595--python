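"""Flexor-extensor synergy sectors of the force-direction cycle.

For one end-point, finds the four force directions where a joint torque
changes sign, lists the sectors of coinciding (TCD) and opposing (TOD)
torque direction with their muscle patterns, and prints the sector
weights, which depend only on the elbow angle.
"""

import math

from armstat import (
    ArmGeometry,
    JointConfiguration,
    characteristic_angles,
    synergy_profile,
)

ca = characteristic_angles(ArmGeometry(), JointConfiguration(0.0, math.pi / 2))
profile = synergy_profile(ca)

print("force singular points (rad):",
      ", ".join(f"{p:.4f}" for p in profile.fsp))
print("sectors over one force turn:")
for s in profile.sectors:
    print(f"  [{s.start:.4f}, {s.end:.4f})  {s.label}  {s.klass}  "
          f"shoulder {s.shoulder_muscle}, elbow {s.elbow_muscle}")
print(f"weights: w_TCD = {profile.w_tcd:.3f}, w_TOD = {profile.w_tod:.3f}")
print("  -> with a right-angle elbow, same-function muscle pairs "
      "(flexor-flexor or extensor-extensor) carry 75% of the cycle")
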