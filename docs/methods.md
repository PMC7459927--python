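# Methods

## Model

The package implements a static, sagittal-plane model of the stoop lift
(legs straight, trunk flexed forward, arms vertical, no torsion, no
acceleration). The body above the L5-S1 intervertebral joint is a rigid
lever pivoting at L5-S1; the erector spinae, acting on a short moment arm
(≈5 cm, 2.98% of stature H), balances the flexor moments of the head-neck,
both arms, the trunk above L5-S1, and the held object.

Geometry. The object's centre of gravity sits h cm above the ground in the
hands of straight, vertical arms, so the acromion sits at height h + H2 and
the trunk inclination α (measured from the horizontal, 0 < α ≤ 90°)
satisfies

    cos α = (h/H + b − a) / k2

with a = H1/H the L5-S1 (anterior superior iliac spine) height fraction,
b = H2/H the functional arm-length fraction, and k2 the acromion–L5-S1
distance fraction. The feasible interval is [H·(a−b), H·(a−b+k2)): the lower
bound is full flexion (α = 90°, the trunk horizontal), the open upper bound
would be a fully upright trunk (α = 0), which the model statement excludes.

Moment balance. With weight fractions j1 (head-neck), j2 (both arms), j3
(trunk above L5-S1) and lever fractions k1, k2, k3, the balance solves to

    F = (c1·M + c2·G) · sin α,
    c1 = (j1·k1 + j2·k2 + j3·k3) / e,   c2 = k2 / e,

where e is the erector moment-arm fraction, M the body weight-force (N) and
G the object weight (N). An intra-abdominal pressure term (force 1% M on a
6.8% H arm) assists extension; the reference closed form drops it, so it is
off by default and available via `include_abdominal` (worth ≈13 N for the
standard worker).

Recommended weight limit. The NIOSH revised lifting equation is adapted to
Chinese male anthropometry: load constant 20 kg (15% below 23), vertical
reference 72 cm (from 75). The bundled single-lift scenario fixes the
horizontal multiplier at 1 (25 cm), asymmetry 0, frequency multiplier 1
(0.2 lifts/min, ≤1 h shift), coupling 0.90 (hard to grasp), and ties the
vertical travel to the 50th-percentile functional hand height:
D = 74 − h cm. Two deliberate deviations from the NIOSH application manual:
D is not clamped to ≥25 cm and HM/VM are not capped, because the adapted
form evaluates D down to 2 cm and only the unclamped equation reproduces the
reference values. Lifts at or above 74 cm are outside the adapted model (the
travel vanishes); this limit is inherent to tying D to the hand height and
is surfaced as a domain error, not worked around.

Comfort and risk. Discomfort is μC = F / F(RWL) — the force relative to
what the same posture needs at the limit load — and comfort C = 1 − μC.
Since F is affine in G, C is linear in the lifted mass and crosses zero
exactly at mass = RWL (lifting index LI = 1). Classes: LI < 1 acceptable,
LI = 1 limit, LI > 1 dangerous, LI > 3 severely dangerous. The slope dF/dLI
is c2·RWL·g·sin α, ≈1300 N per unit LI at mid-range heights.

Spinal check. The L5-S1 reaction splits into a normal component
σ = F + (w·M + G)·cos α and shear τ = (w·M + G)·sin α, w = 0.47 being the
upper-body weight fraction; the resultant √(σ² + τ²) is compared with the
(overridable) 3400 N NIOSH compression criterion. The model's
self-consistency check evaluates the resultant at G = RWL(h) across the
working-height grid: it spans 2652.6–3376.7 N, always below the criterion.

## Parameters and provenance

All constants trace to the bundled 10-row body-segment inertial table
(GB/T 17245-2004 male averages) and GB10000-88 50th-percentile dimensions:

| symbol | value | meaning |
|---|---|---|
| H | 168 cm | stature (whole-body centroid row: 734.2/0.438 = 1676 mm) |
| M | 578 N | weight-force (59 kg × 9.8) |
| a | 0.54 | L5-S1 height / H (iliac spine at 909 mm, taken as 90 cm) |
| b | 0.37 | functional arm length / H (1367 − 741 = 626 mm) |
| k1, k2, k3 | 0.39, 0.27, 0.15 | head-centroid, acromion, trunk-centroid lever fractions |
| j1, j2, j3 | 0.0862, 0.0864, 0.30 | head-neck, both-arms, trunk weight fractions |
| e | 0.0298 | erector moment arm / H (≈5 cm) |
| w | 0.47 | upper-body weight fraction in the stress split |

g = 9.8 m/s² exactly, everywhere; the published convention also rounds
weight-forces to whole newtons (59 kg → 578 N), and custom profiles in
published mode follow it.

Two parameter modes exist because the reference results are printed from
the *rounded* constants. `published` (default) uses the two-decimal
published values — including cos α = 3.70·h/H − 0.63 and (c1, c2) =
(3.42, 9.06) — and reproduces every reference number to its printed
precision. `derived` recomputes everything unrounded from the segment table
(a = 0.5424, k2 = 0.2733, c1 = 3.4210, …) for sensitivity analysis. The two
modes agree within ≈0.5% over most of the height range but diverge to ≈2%
near the upper end, where sin α is small and most sensitive to the cosine
rounding; this spread is an honest picture of the rounding sensitivity, not
an implementation artifact. The segment table itself contains one internal
inconsistency: the foot's centroid relative position is 48.6% in the table
but one derivation text uses 38.2%; the table value is used (it alone
reconstructs the 909 mm iliac-spine height).

Numerical choices. The closed upper bound of the posture interval is
excluded with a 1e-12 guard on cos α so the boundary height itself never
passes as in-range through float rounding. Heights within 0.05 cm (the
tables' print precision) below the lower bound are snapped to the bound
(cos α = 0) instead of rejected, so the printed bound 28.6 cm is usable even
though the exact rounded-mode bound is 28.605 cm. Out-of-range heights are
explicit errors, never silently clamped — clamping would fabricate forces
outside the model's stated domain. The frequency-multiplier table is a
discrete lookup (no interpolation; the optional conservative mode rounds an
untabulated rate up to the next tabulated row). The "limit" comfort class
uses a 1e-9 relative tolerance on LI; it is a measure-zero boundary kept for
the taxonomy.

## Testing and the synthetic fixtures

The torque balance is verified along two independent paths: the closed form
against `torque_balance_oracle`, which re-sums the individual lever moments
term by term and never calls the closed form; they agree to relative 1e-12.
Property tests (hypothesis, derandomised) cover monotonicity of F in load
and height, the strict increase of RWL in height, the Pythagorean closure of
the stress split, the sign consistency of comfort with the lifting index,
and scale invariance of the posture in h/H.

`generate_fixture_tasks` emulates a shift's worth of lifting tasks:
statures uniform in 155–190 cm, body masses 50–95 kg (a plausible adult male
working population around the 168 cm/59 kg reference), object heights inside
each worker's feasible range, and object masses in [0, 2]×RWL so assessments
span both risk sides. It does not emulate measurement noise, repeated lifts
by one worker, posture variation, or any correlation between stature and
mass — passing batch tests therefore shows the pipeline is consistent and
total, not that the model predicts real injury outcomes.

Problem sizes: all reference quantities are desk-scale (a 39-point height
grid); the default test suite and the acceptance script each run in seconds.

## Limitations

- Static stoop only: no squat, no dynamics, no torsion or asymmetric
  postures (the asymmetry multiplier exists but the geometry is sagittal).
- Male 50th-percentile segment fractions only; custom profiles rescale
  stature/weight but keep those fractions, so they do not represent female
  or extreme-percentile segment geometry.
- L5-S1 height is approximated by the anterior superior iliac spine height;
  k2 = 0.27 is the published rounding of 46/168 ≈ 0.274.
- Comfort covers muscle loading only; psychological and environmental
  comfort factors are out of scope, and the LI–injury-risk relation is not
  modelled (it is known to be non-linear).
- The lifting-index classes are thresholds, not probabilities of injury.
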