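"""L5-S1 load decomposition and the 3400 N compression check.

The joint reaction at L5-S1 combines the erector spinae pull F (acting along
the trunk) with the weight of everything above the joint (0.47*M by the
bundled convention) plus the object weight G.  Resolved along and across the
disc axis:

    sigma = F + (w*M + G) * cos(alpha)      normal (compressive) component
    tau   =     (w*M + G) * sin(alpha)      shear component
    N     = sqrt(sigma^2 + tau^2)           resultant

with w = upper_body_weight_frac.  The NIOSH action limit treats resultants
below 3400 N as not injurious to the lumbar spine; the criterion is a named,
overridable constant, never hard-coded in logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anthropometry import AnthropometricProfile, standard_profile, GRAVITY
from .errors import DomainError
from .posture_force import PostureState, erector_force
from .rwl import rwl_chinese

#: NIOSH maximum acceptable L5-S1 compression (N)
COMPRESSION_CRITERION_N = 3400.0


@dataclass(frozen=True)
class StressState:
    """Normal/shear/resultant load on L5-S1 for one lift."""

    normal_sigma: float  # N
    shear_tau: float  # N
    resultant_N: float  # N
    posture: PostureState
    below_criterion: bool
    criterion: float = COMPRESSION_CRITERION_N

    def to_dict(self) -> dict:
        return {
            "object_height_cm": self.posture.object_height_h,
            "sigma_N": self.normal_sigma,
            "tau_N": self.shear_tau,
            "resultant_N": self.resultant_N,
            "criterion_N": self.criterion,
            "below_criterion": self.below_criterion,
        }


@dataclass(frozen=True)
class ValidationReport:
    """Grid evaluation of the L5-S1 resultant at the limit load (C = 0)."""

    states: tuple  # of (h_cm, rwl_kg, StressState)
    min_resultant: float
    h_at_min: float
    max_resultant: float
    h_at_max: float
    all_below_criterion: bool
    criterion: float

    def rows(self) -> list[dict]:
        out = []
        for h, rwl_kg, st in self.states:
            d = st.to_dict()
            d["rwl_kg"] = rwl_kg
            out.append(d)
        return out


def stress_decomposition(G: float, h: float,
                         profile: AnthropometricProfile | None = None,
                         mode: str = "published",
                         criterion: float = COMPRESSION_CRITERION_N) -> StressState:
    """sigma, tau and resultant N at L5-S1 for object weight ``G`` (N)."""
    profile = profile or standard_profile()
    res = erector_force(G, h, profile, mode)  # closed-form F, abdominal off
    w = profile.upper_body_weight_frac
    body_plus_load = w * profile.weight_force_M + G
    sigma = res.erector_force_F + body_plus_load * res.posture.cos_alpha
    tau = body_plus_load * res.posture.sin_alpha
    resultant = math.hypot(sigma, tau)
    return StressState(sigma, tau, resultant, res.posture,
                       resultant < criterion, criterion)


def validate_at_rwl(profile: AnthropometricProfile | None = None,
                    h_grid=None, criterion: float = COMPRESSION_CRITERION_N,
                    mode: str = "published") -> ValidationReport:
    """Evaluate the L5-S1 resultant at G = RWL(h) across ``h_grid`` (cm).

    This is the model's self-consistency check: at comfort C = 0 the
    recommended load must keep the resultant below the criterion everywhere.
    """
    profile = profile or standard_profile()
    if h_grid is None:
        h_grid = list(range(34, 73))
    h_grid = list(h_grid)
    if not h_grid:
        raise DomainError("empty height grid")
    states = []
    for h in h_grid:
        rwl_kg = rwl_chinese(h, profile, mode).rwl_kg
        st = stress_decomposition(rwl_kg * GRAVITY, h, profile, mode, criterion)
        states.append((float(h), rwl_kg, st))
    min_h, _, min_st = min(states, key=lambda t: t[2].resultant_N)
    max_h, _, max_st = max(states, key=lambda t: t[2].resultant_N)
    return ValidationReport(
        states=tuple(states),
        min_resultant=min_st.resultant_N, h_at_min=min_h,
        max_resultant=max_st.resultant_N, h_at_max=max_h,
        all_below_criterion=all(s.below_criterion for _, _, s in states),
        criterion=criterion)
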