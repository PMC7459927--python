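"""Waist comfort score and lifting-index classification.

Discomfort is the erector spinae force relative to the force the same
posture would need at the recommended limit load:

    muC = F / F(RWL),    C = 1 - muC

C is 1 at zero effort (never reached: the trunk's own weight keeps F > 0),
crosses 0 exactly at the limit load (lifting index LI = actual mass / RWL
equal to 1) and goes negative for dangerous loads.  LI > 3 marks greatly
elevated risk.  Because F is affine in the object weight, C is linear in
the lifted mass at fixed height.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anthropometry import AnthropometricProfile, standard_profile, GRAVITY
from .errors import DomainError
from .posture_force import erector_force
from .rwl import rwl_chinese

CATEGORIES = ("acceptable", "limit", "dangerous", "severely_dangerous")

#: LI above this is classed severely dangerous (strictly greater)
SEVERE_LI = 3.0


@dataclass(frozen=True)
class ComfortAssessment:
    """Full comfort/risk readout for one lift."""

    erector_force_F: float  # N
    erector_force_at_rwl: float  # N
    discomfort_muC: float
    comfort_C: float
    lifting_index_LI: float
    category: str
    rwl_kg: float
    object_mass_kg: float
    object_height_cm: float

    def to_dict(self) -> dict:
        return {
            "object_mass_kg": self.object_mass_kg,
            "object_height_cm": self.object_height_cm,
            "rwl_kg": self.rwl_kg,
            "erector_force_N": self.erector_force_F,
            "erector_force_at_rwl_N": self.erector_force_at_rwl,
            "discomfort_muC": self.discomfort_muC,
            "comfort_C": self.comfort_C,
            "lifting_index_LI": self.lifting_index_LI,
            "category": self.category,
        }


def classify(li: float, tol: float = 1e-9) -> str:
    """Load-risk category from the lifting index.

    The ``limit`` class (LI = 1, C = 0) is a measure-zero boundary kept to
    mirror the model's taxonomy; ``tol`` is the relative half-width that
    counts as "at the limit".
    """
    if li < 0:
        raise DomainError("lifting index cannot be negative")
    if li > SEVERE_LI:
        return "severely_dangerous"
    if li > 1.0 + tol:
        return "dangerous"
    if li >= 1.0 - tol:
        return "limit"
    return "acceptable"


def force_at_rwl(h: float, profile: AnthropometricProfile | None = None,
                 mode: str = "published") -> float:
    """Erector force F(RWL) (N): the force when lifting exactly RWL at ``h``."""
    profile = profile or standard_profile()
    g_rwl = rwl_chinese(h, profile, mode).rwl_kg * GRAVITY
    return erector_force(g_rwl, h, profile, mode).erector_force_F


def assess(object_mass_kg: float, h: float,
           profile: AnthropometricProfile | None = None,
           mode: str = "published",
           tol: float = 1e-9) -> ComfortAssessment:
    """Comfort, discomfort, LI and risk category for one lift."""
    profile = profile or standard_profile()
    if object_mass_kg < 0:
        raise DomainError("object mass must be non-negative")
    rwl = rwl_chinese(h, profile, mode).rwl_kg
    F = erector_force(object_mass_kg * GRAVITY, h, profile, mode).erector_force_F
    F_rwl = erector_force(rwl * GRAVITY, h, profile, mode).erector_force_F
    mu = F / F_rwl
    # LI as a mass ratio; identical to the weight-force ratio since g is
    # one constant, but avoids a kg->N->kg round trip
    li = object_mass_kg / rwl
    return ComfortAssessment(
        erector_force_F=F, erector_force_at_rwl=F_rwl,
        discomfort_muC=mu, comfort_C=1.0 - mu,
        lifting_index_LI=li, category=classify(li, tol),
        rwl_kg=rwl, object_mass_kg=object_mass_kg, object_height_cm=h)


def force_per_li(h: float, profile: AnthropometricProfile | None = None,
                 mode: str = "published") -> float:
    """Slope dF/dLI (N per unit lifting index) at height ``h``.

    F is affine in the object weight, so raising LI by 1 adds exactly
    c2 * RWL * g * sin(alpha) newtons — about 1300 N at mid-range heights
    for the standard worker.
    """
    profile = profile or standard_profile()
    rwl = rwl_chinese(h, profile, mode).rwl_kg
    zero = erector_force(0.0, h, profile, mode)
    c2 = zero.coefficients[1]
    return c2 * rwl * GRAVITY * zero.posture.sin_alpha
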