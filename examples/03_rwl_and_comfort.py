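"""Recommended weight limit and the waist comfort score for one lift.

The China-adapted NIOSH limit RWL(h) = 20*(1-0.003|h-72|)*(0.82+4.5/(74-h))*0.90
kg rises with the object height; comfort C = 1 - F/F(RWL) is positive below
the limit, zero at it, negative above.
"""

from waistload import assess, rwl_chinese

h = 70.0
res = rwl_chinese(h)
print(f"RWL at h = {h:.0f} cm: {res.rwl_kg:.2f} kg")
print("  multipliers:", {k: round(v, 3) for k, v in res.multipliers.items()})

for mass in (10.0, res.rwl_kg, 50.0):
    a = assess(mass, h)
    print(f"lifting {mass:5.2f} kg:  LI = {a.lifting_index_LI:4.2f}"
          f"  C = {a.comfort_C:+.3f}  -> {a.category}")
# LI < 1 (C > 0) is an acceptable load, LI = 1 the limit load, LI > 1 a
# dangerous one; LI > 3 would mark greatly elevated risk.  The limit class
# is a knife-edge: any mass above the exact RWL classifies as dangerous.
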