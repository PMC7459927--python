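"""NIOSH revised lifting equation and its Chinese adaptation.

The recommended weight limit (RWL, kg) is a load constant discounted by six
multipliers:

    RWL = LC * HM * VM * DM * FM * AM * CM

    HM = 25 / horizontal_dist          (cm, palm to ankle midpoint)
    VM = 1 - 0.003 * |V - v_ref|       (V = hand height at origin, cm)
    DM = 0.82 + 4.5 / D                (D = vertical travel, cm)
    FM = table lookup                  (lift rate x shift duration)
    AM = 1 - 0.0032 * A                (A = asymmetry angle, deg)
    CM = coupling quality in {1.00, 0.95, 0.90}

The Chinese adaptation (GB/T 310020.1-2014 conventions) lowers the load
constant from 23 to 20 kg and the vertical reference from 75 to 72 cm; the
single-lift scenario then fixes HM = 1 (horizontal distance 25 cm), A = 0,
FM = 1 (0.2 lifts/min, <= 1 h) and CM = 0.90 (hard-to-grasp object), and
ties the travel to the 74 cm 50th-percentile functional hand height:
D = 74 - h, giving the closed form in the object height h

    RWL(h) = 20 * (1 - 0.003*|h - 72|) * (0.82 + 4.5/(74 - h)) * 0.90

Deliberate deviations from the NIOSH application manual: D is not clamped to
>= 25 cm and HM/VM are not capped, because the adapted form evaluates D down
to 2 cm; only the unclamped equation reproduces the reference values.  Lifts
with hand height at or above 74 cm are outside the adapted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .anthropometry import AnthropometricProfile, standard_profile
from .errors import DomainError, HeightRangeError, TableLookupError
from . import posture_force

DURATION_CLASSES = ("<=1h", "<=2h", "<=8h")
COUPLING_VALUES = (1.00, 0.95, 0.90)

#: 50th-percentile male functional hand height (cm); travel D = HAND_HEIGHT - h
HAND_HEIGHT_CM = 74.0

MULTIPLIER_NAMES = ("HM", "VM", "DM", "FM", "AM", "CM")


@dataclass(frozen=True)
class LiftConditions:
    """NIOSH task descriptors for one lift."""

    horizontal_dist: float = 25.0  # cm
    vertical_origin_V: float = 75.0  # cm
    travel_D: float = 25.0  # cm
    frequency: float = 0.2  # lifts/min
    duration_class: str = "<=1h"
    asymmetry_A: float = 0.0  # degrees
    coupling_CM: float = 1.00
    load_constant: float = 23.0  # kg
    vm_reference: float = 75.0  # cm

    def __post_init__(self):
        if self.horizontal_dist <= 0:
            raise DomainError("horizontal distance must be positive")
        if self.travel_D < 0:
            raise DomainError("vertical travel must be non-negative")
        if self.frequency < 0.2:
            raise DomainError("lift frequency below 0.2/min is not tabulated")
        if self.duration_class not in DURATION_CLASSES:
            raise DomainError(
                f"duration class {self.duration_class!r} not in {DURATION_CLASSES}")
        if not any(abs(self.coupling_CM - c) < 1e-12 for c in COUPLING_VALUES):
            raise DomainError(
                f"coupling multiplier {self.coupling_CM} not in {COUPLING_VALUES}")


@dataclass(frozen=True)
class RwlResult:
    """Recommended weight limit with its multiplier breakdown."""

    rwl_kg: float
    multipliers: dict = field(default_factory=dict)  # HM..CM

    def to_dict(self) -> dict:
        return {"rwl_kg": self.rwl_kg, **self.multipliers}


@lru_cache(maxsize=1)
def _fm_frame() -> pd.DataFrame:
    path = resources.files("waistload.data").joinpath("frequency_multipliers.csv")
    with path.open() as f:
        return pd.read_csv(f)


def tabulated_frequencies() -> tuple[float, ...]:
    return tuple(sorted(_fm_frame()["frequency_per_min"].unique()))


def frequency_multiplier(frequency: float, duration_class: str = "<=1h",
                         V: float = 75.0, conservative: bool = False) -> float:
    """FM lookup for a lift rate (lifts/min), shift duration and hand height.

    The table is discrete: untabulated rates raise unless ``conservative``
    maps the rate up to the next tabulated (higher-discount) row.
    """
    if V < 0:
        raise DomainError("hand height V must be non-negative")
    if duration_class not in DURATION_CLASSES:
        raise DomainError(
            f"duration class {duration_class!r} not in {DURATION_CLASSES}")
    rates = tabulated_frequencies()
    match = [r for r in rates if abs(r - frequency) < 1e-9]
    if not match:
        if conservative:
            higher = [r for r in rates if r > frequency]
            if not higher:
                raise TableLookupError(
                    f"lift frequency {frequency}/min above the tabulated "
                    f"maximum {rates[-1]}/min")
            match = [higher[0]]
        else:
            raise TableLookupError(
                f"lift frequency {frequency}/min is not tabulated; "
                f"tabulated rates: {rates}")
    band = "V<75" if V < 75 else "V>=75"
    df = _fm_frame()
    row = df[(df["frequency_per_min"] == match[0])
             & (df["duration_class"] == duration_class)
             & (df["v_band"] == band)]
    return float(row["fm"].iloc[0])


def rwl_niosh(conditions: LiftConditions,
              conservative_fm: bool = False) -> RwlResult:
    """RWL (kg) from the generic revised lifting equation."""
    c = conditions
    if c.travel_D == 0:
        raise DomainError("vertical travel D = 0: distance multiplier diverges")
    hm = 25.0 / c.horizontal_dist
    vm = 1.0 - 0.003 * abs(c.vertical_origin_V - c.vm_reference)
    if vm <= 0:
        raise DomainError(
            f"hand height V={c.vertical_origin_V} cm too far from the "
            f"{c.vm_reference} cm reference: VM={vm:.3f} <= 0")
    dm = 0.82 + 4.5 / c.travel_D
    fm = frequency_multiplier(c.frequency, c.duration_class,
                              c.vertical_origin_V, conservative_fm)
    am = 1.0 - 0.0032 * c.asymmetry_A
    if am <= 0:
        raise DomainError(f"asymmetry angle {c.asymmetry_A} deg gives AM <= 0")
    cm = c.coupling_CM
    mult = dict(zip(MULTIPLIER_NAMES, (hm, vm, dm, fm, am, cm)))
    rwl = c.load_constant
    for v in mult.values():
        rwl *= v
    return RwlResult(rwl, mult)


def chinese_conditions(h: float) -> LiftConditions:
    """The adapted single-lift conditions for hand height ``h`` cm."""
    return LiftConditions(horizontal_dist=25.0, vertical_origin_V=float(h),
                          travel_D=HAND_HEIGHT_CM - h, frequency=0.2,
                          duration_class="<=1h", asymmetry_A=0.0,
                          coupling_CM=0.90, load_constant=20.0,
                          vm_reference=72.0)


def rwl_chinese(h: float, profile: AnthropometricProfile | None = None,
                mode: str = "published") -> RwlResult:
    """China-adapted RWL (kg) for an object centred ``h`` cm above ground.

    Valid for h between the posture model's lower bound and the 74 cm
    functional hand height (exclusive, where the travel D vanishes).
    """
    profile = profile or standard_profile()
    if h >= HAND_HEIGHT_CM:
        raise DomainError(
            f"object height {h} cm is at or above the {HAND_HEIGHT_CM:.0f} cm "
            "functional hand height; the adapted model does not cover it")
    lo, hi = posture_force.valid_height_range(profile, mode)
    if not posture_force.trunk_cosine(h, profile, mode).in_range:
        raise HeightRangeError(h, lo, min(hi, HAND_HEIGHT_CM))
    return rwl_niosh(chinese_conditions(h))
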