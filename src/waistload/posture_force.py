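"""Static sagittal-plane torque balance about L5-S1.

A worker in stoop posture (legs straight, trunk flexed forward) holds an
object of weight G whose centre of gravity sits h cm above the ground, arms
vertical.  Treating L5-S1 as the fulcrum, the trunk inclination angle alpha
(0 < alpha <= 90 deg from the horizontal) is fixed by the geometry:

    cos(alpha) = (h/H + b - a) / k2

where H is stature, a = H1/H places L5-S1, b = H2/H is the arm length, and
k2 places the acromion.  Balancing the flexor moments of the head-neck, arms,
trunk and load against the erector spinae acting on its short moment arm
(erector_arm_frac * H) collapses to a closed form

    F = (c1 * M + c2 * G) * sin(alpha)

with c1 = (j1*k1 + j2*k2 + j3*k3) / erector_arm_frac and
c2 = k2 / erector_arm_frac.  For the standard profile the published rounded
coefficients are c1 = 3.42 and c2 = 9.06, and the published cosine is
3.70*h/H - 0.63; only these rounded forms reproduce the reference results to
their printed precision, so ``mode="published"`` is the default.
``mode="derived"`` keeps every quantity as the exact fraction.

:func:`torque_balance_oracle` re-derives F from the individual lever terms
without ever touching the closed form; it exists so tests can check the
algebra along an independent path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anthropometry import AnthropometricProfile, standard_profile
from .errors import DomainError, HeightRangeError

MODES = ("published", "derived")

# Heights this close (cm) below the lower posture bound are treated as the
# bound itself: the published bound is printed at 0.1 cm precision, so its
# printed value may sit a few hundredths of a cm outside the exact interval.
_H_SNAP_CM = 0.05


@dataclass(frozen=True)
class PostureState:
    """Trunk inclination implied by an object height."""

    object_height_h: float  # cm above ground
    cos_alpha: float
    sin_alpha: float
    alpha_deg: float
    in_range: bool


@dataclass(frozen=True)
class ForceResult:
    """Erector spinae force and the state it was computed from."""

    erector_force_F: float  # N
    posture: PostureState
    object_weight_G: float  # N
    coefficients: tuple[float, float]  # (c1, c2)

    def to_dict(self) -> dict:
        return {
            "erector_force_N": self.erector_force_F,
            "object_weight_N": self.object_weight_G,
            "object_height_cm": self.posture.object_height_h,
            "alpha_deg": self.posture.alpha_deg,
            "cos_alpha": self.posture.cos_alpha,
            "c1": self.coefficients[0],
            "c2": self.coefficients[1],
        }


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise DomainError(f"unknown mode {mode!r}; expected one of {MODES}")


def _cos_coefficients(profile: AnthropometricProfile, mode: str):
    """(p, q) such that cos(alpha) = p * h/H - q."""
    p = 1.0 / profile.k2
    q = (profile.a - profile.b) / profile.k2
    if mode == "published":
        # published two-decimal rounding (3.70 and 0.63 for the standard
        # profile); generalised the same way for custom fraction sets
        p, q = round(p, 2), round(q, 2)
    return p, q


def trunk_cosine(h: float, profile: AnthropometricProfile | None = None,
                 mode: str = "published") -> PostureState:
    """Trunk posture at object height ``h`` (cm above ground).

    Returns an out-of-range :class:`PostureState` (rather than raising) when
    ``h`` is outside the feasible interval; negative ``h`` is a hard error.
    """
    _check_mode(mode)
    profile = profile or standard_profile()
    if h < 0:
        raise DomainError(f"object height h={h} cm must be non-negative")
    p, q = _cos_coefficients(profile, mode)
    cos_a = p * h / profile.stature_H - q
    if -_H_SNAP_CM * p / profile.stature_H <= cos_a < 0:
        cos_a = 0.0  # height sits at the printed lower bound
    # strict upper comparison with an ulp guard so h = h_max itself is
    # excluded even when rounding lands cos a hair below 1
    in_range = 0.0 <= cos_a < 1.0 - 1e-12
    if not in_range:
        cos_c = min(max(cos_a, -1.0), 1.0)
        return PostureState(h, cos_a, math.sqrt(1 - cos_c * cos_c),
                            math.degrees(math.acos(cos_c)), False)
    sin_a = math.sqrt(1.0 - cos_a * cos_a)
    return PostureState(h, cos_a, sin_a, math.degrees(math.acos(cos_a)), True)


def valid_height_range(profile: AnthropometricProfile | None = None,
                       mode: str = "published") -> tuple[float, float]:
    """Feasible object-height interval [h_min, h_max) in cm.

    h_min solves cos(alpha) = 0 (trunk fully flexed to the model boundary,
    alpha = 90 deg); h_max solves cos(alpha) = 1 and is excluded because
    alpha = 0 is outside the model's 0 < alpha <= 90 statement.
    """
    _check_mode(mode)
    profile = profile or standard_profile()
    p, q = _cos_coefficients(profile, mode)
    return (q / p * profile.stature_H, (1 + q) / p * profile.stature_H)


def force_coefficients(profile: AnthropometricProfile | None = None,
                       mode: str = "published") -> tuple[float, float]:
    """(c1, c2) of F = (c1*M + c2*G)*sin(alpha)."""
    _check_mode(mode)
    profile = profile or standard_profile()
    c1 = (profile.j1 * profile.k1 + profile.j2 * profile.k2
          + profile.j3 * profile.k3) / profile.erector_arm_frac
    c2 = profile.k2 / profile.erector_arm_frac
    if mode == "published":
        c1, c2 = round(c1, 2), round(c2, 2)
    return c1, c2


def _abdominal_relief(profile: AnthropometricProfile) -> float:
    """Force reduction (N) from intra-abdominal pressure.

    The intra-abdominal force (abdominal_force_frac * M) acting on its lever
    (abdominal_arm_frac * H) assists extension, reducing the erector demand
    by F4*L4 / erector arm.  The closed form drops this term; it is exposed
    behind ``include_abdominal`` for sensitivity checks.
    """
    return (profile.abdominal_force_frac * profile.abdominal_arm_frac
            / profile.erector_arm_frac) * profile.weight_force_M


def erector_force(G: float, h: float,
                  profile: AnthropometricProfile | None = None,
                  mode: str = "published",
                  include_abdominal: bool = False) -> ForceResult:
    """Erector spinae force F (N) for object weight ``G`` (N) at height ``h``.

    Raises :class:`HeightRangeError` when ``h`` is outside the feasible
    interval and :class:`DomainError` for negative loads.
    """
    profile = profile or standard_profile()
    if G < 0:
        raise DomainError(f"object weight G={G} N must be non-negative")
    posture = trunk_cosine(h, profile, mode)
    if not posture.in_range:
        lo, hi = valid_height_range(profile, mode)
        raise HeightRangeError(h, lo, hi)
    c1, c2 = force_coefficients(profile, mode)
    F = (c1 * profile.weight_force_M + c2 * G) * posture.sin_alpha
    if include_abdominal:
        F -= _abdominal_relief(profile)
    return ForceResult(F, posture, G, (c1, c2))


def torque_balance_oracle(G: float, h: float,
                          profile: AnthropometricProfile | None = None,
                          include_abdominal: bool = False) -> float:
    """F (N) rebuilt lever-by-lever; independent of :func:`erector_force`.

    Sums the flexor moments of the head-neck (j1*M on arm k1*H*sin a), both
    arms (j2*M on k2*H*sin a), the trunk above L5-S1 (j3*M on k3*H*sin a)
    and the load (G on k2*H*sin a), optionally subtracts the intra-abdominal
    moment F4*L4, and divides by the erector moment arm.  Uses the exact
    (unrounded) geometry throughout.
    """
    profile = profile or standard_profile()
    if G < 0:
        raise DomainError(f"object weight G={G} N must be non-negative")
    posture = trunk_cosine(h, profile, mode="derived")
    if not posture.in_range:
        lo, hi = valid_height_range(profile, mode="derived")
        raise HeightRangeError(h, lo, hi)
    H, M = profile.stature_H, profile.weight_force_M
    sin_a = posture.sin_alpha
    moment = 0.0
    for j, k in ((profile.j1, profile.k1), (profile.j2, profile.k2),
                 (profile.j3, profile.k3)):
        moment += (j * M) * (k * H * sin_a)
    moment += G * (profile.k2 * H * sin_a)
    if include_abdominal:
        moment -= (profile.abdominal_force_frac * M) * (profile.abdominal_arm_frac * H)
    return moment / (profile.erector_arm_frac * H)
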