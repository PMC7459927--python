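"""Body-segment parameters and worker profiles.

The model's geometry and mass distribution come from the Chinese national
standards for adult male body-segment inertial parameters (GB/T 17245-2004)
and human dimensions (GB10000-88).  The bundled segment table lists, for each
body segment, the centroid position (mm from the stated measurement start
point), the centroid's relative position along the segment (%), and the
segment's relative mass (% of whole-body mass).

From that table the module derives every constant the torque-balance model
needs, packaged as an :class:`AnthropometricProfile`:

``a``   L5-S1 height over stature (H1/H; L5-S1 is taken at the height of the
        anterior superior iliac spine — an approximation, not a derivation)
``b``   functional arm length over stature (H2/H)
``k1..k3``  lever-arm fractions of stature for the head-neck centroid,
        acromion, and trunk centroid, all measured from L5-S1
``j1..j3``  weight fractions of the head-neck, both arms, and the trunk
        above L5-S1
``erector_arm_frac``  erector spinae moment arm (≈5 cm) over stature
``abdominal_arm_frac`` / ``abdominal_force_frac``  intra-abdominal pressure
        lever arm and force, as fractions of stature and body weight
``upper_body_weight_frac``  weight of everything above L5-S1 over body
        weight, used by the spinal stress decomposition (0.47 by convention;
        the exact j1+j2+j3 sum is 0.4726)

Two parameter sets are available.  ``published`` (default) carries the
published two-decimal constants, which are the only set that reproduces the
reference results to their printed precision.  ``derived`` recomputes every
fraction unrounded from the segment table and the raw GB dimensions, for
sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

from .errors import DomainError, TableLookupError

#: standard gravity used for every kg <-> N conversion in the package
GRAVITY = 9.8  # m/s^2

# Raw GB10000-88 male 50th-percentile dimensions (mm) used by derived mode.
_SHOULDER_HEIGHT_MM = 1367.0
_HAND_FUNCTIONAL_HEIGHT_MM = 741.0


@dataclass(frozen=True)
class SegmentInertia:
    """One row of the body-segment inertial-parameter table."""

    segment_name: str
    centroid_position: float  # mm from the measurement start point
    centroid_relative_position: float  # % of segment length
    relative_mass: float | None  # % of whole-body mass (None for "Whole")

    def __post_init__(self):
        if not (0 < self.centroid_relative_position < 100):
            raise DomainError(
                f"{self.segment_name}: relative position must be in (0, 100)%"
            )
        if self.relative_mass is not None and not (0 < self.relative_mass <= 100):
            raise DomainError(
                f"{self.segment_name}: relative mass must be in (0, 100]%"
            )


@dataclass(frozen=True)
class AnthropometricProfile:
    """A worker's stature, weight-force and all model fractions."""

    stature_H: float  # cm
    weight_force_M: float  # N
    a: float
    b: float
    k1: float
    k2: float
    k3: float
    j1: float
    j2: float
    j3: float
    erector_arm_frac: float
    abdominal_arm_frac: float
    abdominal_force_frac: float
    upper_body_weight_frac: float

    def __post_init__(self):
        if self.stature_H <= 0 or self.weight_force_M <= 0:
            raise DomainError("stature and weight-force must be positive")
        for name in ("a", "b", "k1", "k2", "k3", "j1", "j2", "j3",
                     "erector_arm_frac", "abdominal_arm_frac",
                     "abdominal_force_frac", "upper_body_weight_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise DomainError(f"fraction {name}={v} must be in (0, 1)")
        if self.a <= self.b:
            # otherwise cos(alpha) never crosses zero at a positive height
            # and the valid lifting-height interval is empty
            raise DomainError("profile requires a > b (L5-S1 above arm reach)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AnthropometricProfile":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "AnthropometricProfile":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_yaml(cls, s: str) -> "AnthropometricProfile":
        return cls.from_dict(yaml.safe_load(s))


@lru_cache(maxsize=1)
def _segment_frame() -> pd.DataFrame:
    with resources.files("waistload.data").joinpath("segment_inertia.csv").open() as f:
        return pd.read_csv(f)


@lru_cache(maxsize=1)
def segment_table() -> tuple[SegmentInertia, ...]:
    """The bundled 10-row body-segment inertial table (male, 18-60 y)."""
    rows = []
    for _, r in _segment_frame().iterrows():
        rows.append(SegmentInertia(
            segment_name=r["segment"],
            centroid_position=float(r["centroid_position_mm"]),
            centroid_relative_position=float(r["relative_position_pct"]),
            relative_mass=None if pd.isna(r["relative_mass_pct"])
            else float(r["relative_mass_pct"]),
        ))
    return tuple(rows)


def _segment(name: str, segments=None) -> SegmentInertia:
    for s in (segments or segment_table()):
        if s.segment_name.lower() == name.lower():
            return s
    raise TableLookupError(f"no segment named {name!r} in the inertial table")


def reference_stature(whole_centroid_position: float,
                      whole_relative_position: float) -> float:
    """Stature (mm) implied by the whole-body centroid row.

    The whole-body centroid sits ``whole_relative_position`` of the way down
    from the vertex, at ``whole_centroid_position`` mm, so stature is their
    quotient.  ``whole_relative_position`` is a fraction in (0, 1).
    """
    if not (0 < whole_relative_position < 1):
        raise DomainError("relative position must be a fraction in (0, 1)")
    if whole_centroid_position <= 0:
        raise DomainError("centroid position must be positive")
    return whole_centroid_position / whole_relative_position


def iliac_spine_height(segments=None) -> float:
    """Standing height (mm) of the anterior superior iliac spine.

    Each leg segment's length is reconstructed from its distal-referenced
    centroid position p and relative position r (measured from the proximal
    end) as p/(1 - r); stacking thigh + lower leg + foot gives the iliac
    spine height, the model's stand-in for the L5-S1 height.
    """
    total = 0.0
    for name in ("Thigh", "A lower leg", "Foot"):
        s = _segment(name, segments)
        total += s.centroid_position / (1 - s.centroid_relative_position / 100)
    return total


def _published_fractions() -> dict:
    # the published two-decimal constants; only these reproduce the
    # reference results to their printed precision
    return dict(a=0.54, b=0.37, k1=0.39, k2=0.27, k3=0.15,
                j1=0.0862, j2=0.0864, j3=0.30,
                erector_arm_frac=0.0298, abdominal_arm_frac=0.068,
                abdominal_force_frac=0.01, upper_body_weight_frac=0.47)


def _derived_fractions() -> dict:
    """Unrounded fractions recomputed from the segment table and GB dims."""
    H_mm = reference_stature(
        _segment("Whole").centroid_position,
        _segment("Whole").centroid_relative_position / 100)
    iliac = iliac_spine_height()
    neck = _segment("Neck")
    j1 = neck.relative_mass / 100
    j2 = 2 * sum(_segment(n).relative_mass for n in
                 ("Upper arm", "Forearm", "Hand")) / 100
    head_neck_len = neck.centroid_position / (neck.centroid_relative_position / 100)
    ad = (H_mm - iliac) - neck.centroid_position          # head centroid to L5-S1
    ac = _SHOULDER_HEIGHT_MM - iliac                      # acromion to L5-S1
    ab = (H_mm - head_neck_len - iliac) / 2               # trunk centroid to L5-S1
    h2 = _SHOULDER_HEIGHT_MM - _HAND_FUNCTIONAL_HEIGHT_MM  # functional arm length
    return dict(a=iliac / H_mm, b=h2 / H_mm,
                k1=ad / H_mm, k2=ac / H_mm, k3=ab / H_mm,
                j1=j1, j2=j2, j3=0.30,
                erector_arm_frac=50.0 / H_mm,
                abdominal_arm_frac=114.3 / H_mm,
                abdominal_force_frac=0.01,
                upper_body_weight_frac=j1 + j2 + 0.30)


def standard_profile(mode: str = "published") -> AnthropometricProfile:
    """The 50th-percentile Chinese adult male profile (H=168 cm, 59 kg).

    ``mode="published"`` (default) returns the published constants;
    ``mode="derived"`` recomputes them unrounded from the segment table.
    """
    if mode == "published":
        return AnthropometricProfile(stature_H=168.0, weight_force_M=578.0,
                                     **_published_fractions())
    if mode == "derived":
        H_mm = reference_stature(
            _segment("Whole").centroid_position,
            _segment("Whole").centroid_relative_position / 100)
        return AnthropometricProfile(stature_H=H_mm / 10,
                                     weight_force_M=59.0 * GRAVITY,
                                     **_derived_fractions())
    raise DomainError(f"unknown mode {mode!r}; use 'published' or 'derived'")


def custom_profile(stature_cm: float, mass_kg: float,
                   mode: str = "published") -> AnthropometricProfile:
    """A worker profile with custom stature and body mass.

    All dimensionless fractions are carried over from the standard profile;
    only stature and weight-force scale.  Statures outside [100, 230] cm or
    masses outside [30, 200] kg are rejected.  In published mode the
    weight-force follows the published whole-newton convention
    (59 kg -> 578 N); derived mode keeps mass*g unrounded.
    """
    if not (100 <= stature_cm <= 230):
        raise DomainError(f"stature {stature_cm} cm outside [100, 230] cm")
    if not (30 <= mass_kg <= 200):
        raise DomainError(f"body mass {mass_kg} kg outside [30, 200] kg")
    base = standard_profile(mode)
    weight = mass_kg * GRAVITY
    if mode == "published":
        weight = float(round(weight))
    return replace(base, stature_H=float(stature_cm), weight_force_M=weight)
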