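"""The scaled MacLeod-Boynton task space and its white-point anchor.

Computes the MacLeod-Boynton chromaticity of CIE Illuminant C through the
packaged cone fundamentals, maps it into the threshold-scaled plane, and
shows where the hue-circle endpoints and a typical unique-yellow setting sit.
"""

from chromadapt import colorspace as cs
from chromadapt.fundamentals import illuminant_c, task_fundamentals

fund = task_fundamentals()
chroma = cs.mb_chromaticity(cs.cone_absorptions(illuminant_c(), fund))
origin = cs.scale_mb(chroma)

print(f"Illuminant C chromaticity: rmb = {chroma.rmb:.5f}, bmb = {chroma.bmb:.5f}")
print("  (the space is built so this is its origin: nominal values 0.6568, 0.01825)")
print(f"Scaled-space position: LM = {origin.LM:+.2f}, S = {origin.S:+.2f} threshold units")
print("  (within a few detection thresholds of (0, 0))\n")

for label, angle in [("green endpoint", 200.0), ("unique yellow (typ.)", 297.0),
                     ("red endpoint", 360.0)]:
    p = cs.hue_to_scaled_mb(cs.HueSetting(angle))
    print(f"{label:22s} {angle:5.0f} deg -> LM = {p.LM:+7.2f}, S = {p.S:+7.2f}")
print("\nAngles on the radius-80 circle: larger angle = redder stimulus;")
print("the adjustment task lives between 200 deg (green) and 360 deg (red).")
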