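"""Build worker profiles and inspect the anthropometric constants.

The standard profile is the 50th-percentile Chinese adult male (168 cm,
59 kg -> 578 N); custom profiles rescale stature and weight while keeping
the dimensionless segment fractions.
"""

from waistload import custom_profile, iliac_spine_height, reference_stature, standard_profile

std = standard_profile()
print("standard profile:")
print(f"  stature H = {std.stature_H:.0f} cm, weight-force M = {std.weight_force_M:.0f} N")
print(f"  L5-S1 height fraction a = {std.a}, arm-length fraction b = {std.b}")
print(f"  lever fractions k1..k3 = {std.k1}, {std.k2}, {std.k3}")
print(f"  weight fractions j1..j3 = {std.j1}, {std.j2}, {std.j3}"
      f"  (sum {std.j1 + std.j2 + std.j3:.4f}, bundled as {std.upper_body_weight_frac})")

# the derivation chain behind those constants, from the segment table
print(f"  stature from whole-body centroid row: {reference_stature(734.2, 0.438):.0f} mm")
print(f"  iliac spine (≈ L5-S1) standing height: {iliac_spine_height():.0f} mm")

tall = custom_profile(185, 90)
print("custom 185 cm / 90 kg worker:")
print(f"  M = {tall.weight_force_M:.0f} N; fractions unchanged (a = {tall.a})")
# The fractions are population constants: individual differences enter the
# model only through stature and body weight.
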