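"""Exception hierarchy for the lifting model.

All model errors derive from :class:`WaistloadError` so callers (and the
CLI) can catch the whole family; the subclasses distinguish "the value is
nonsensical" from "the value is outside the model's stated domain" from
"the lookup key is not in the bundled table".
"""


class WaistloadError(ValueError):
    """Base class for all model errors."""


class DomainError(WaistloadError):
    """An input is outside the set of values the model is defined on."""


class HeightRangeError(DomainError):
    """A lifting height lies outside the posture-feasible interval."""

    def __init__(self, h_cm: float, h_min: float, h_max: float):
        self.h_cm, self.h_min, self.h_max = h_cm, h_min, h_max
        super().__init__(
            f"object height {h_cm:.2f} cm is outside the valid range "
            f"[{h_min:.1f}, {h_max:.1f}) cm for this worker profile"
        )


class TableLookupError(WaistloadError):
    """A key is absent from a bundled lookup table."""
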