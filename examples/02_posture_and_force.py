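"""Trunk posture and erector spinae force across lifting heights.

For a stoop lift the object height fixes the trunk angle; the torque
balance then gives the erector spinae force F = (3.42 M + 9.06 G) sin(alpha)
for the standard worker.
"""

from waistload import GRAVITY, erector_force, trunk_cosine, valid_height_range

lo, hi = valid_height_range()
print(f"feasible object heights: {lo:.1f} cm <= h < {hi:.1f} cm")

mass_kg = 15.0
print(f"lifting {mass_kg:.0f} kg at various heights:")
for h in (30, 40, 50, 60, 70):
    p = trunk_cosine(h)
    f = erector_force(mass_kg * GRAVITY, h)
    print(f"  h = {h:2d} cm  trunk angle = {p.alpha_deg:5.1f} deg"
          f"  F = {f.erector_force_F:7.1f} N")
# F falls as the object rises: a straighter trunk shortens every flexor
# lever arm, so the muscle needs less force for the same load.
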