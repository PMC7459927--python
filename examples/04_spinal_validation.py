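"""Check L5-S1 loading at the limit load against the 3400 N criterion.

At comfort C = 0 (lifting exactly RWL) the L5-S1 resultant must stay below
the NIOSH 3400 N compression criterion everywhere — the model's internal
consistency check.
"""

from waistload import validate_at_rwl

rep = validate_at_rwl(h_grid=range(34, 73))
print(f"L5-S1 resultant at G = RWL(h), h = 34..72 cm:")
print(f"  minimum {rep.min_resultant:.2f} N at h = {rep.h_at_min:.0f} cm")
print(f"  maximum {rep.max_resultant:.2f} N at h = {rep.h_at_max:.0f} cm")
print(f"  all below {rep.criterion:.0f} N criterion: {rep.all_below_criterion}")

row = next(r for r in rep.rows() if r["object_height_cm"] == 70.0)
print(f"  at 70 cm: sigma = {row['sigma_N']:.1f} N, tau = {row['tau_N']:.1f} N,"
      f" RWL = {row['rwl_kg']:.2f} kg")
# The resultant is dominated by the normal (compressive) component, which
# itself is mostly the erector spinae pull.
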