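"""Per-feature transmission parameters.

A binary feature evolves under two error-prone copying processes: vertical
(intergenerational) transmission with ingress rate p_I (spontaneous gain)
and egress rate p_E (spontaneous loss), and horizontal transmission
(borrowing from a geographic neighbor) with miscopy rates p_I' (absence
copied as presence) and p_E' (presence copied as absence).  The fifth
parameter q is the relative rate of horizontal over vertical events.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureParams:
    """The five per-feature transmission probabilities."""

    p_ingress_vertical: float = 0.0
    p_egress_vertical: float = 0.0
    p_ingress_horizontal: float = 0.0
    p_egress_horizontal: float = 0.0
    q_horizontal_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "p_ingress_vertical", "p_egress_vertical",
            "p_ingress_horizontal", "p_egress_horizontal",
            "q_horizontal_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v!r}")

    @property
    def total_vertical_error(self) -> float:
        """p = p_I + p_E, the total vertical error rate."""
        return self.p_ingress_vertical + self.p_egress_vertical

    @property
    def total_horizontal_error(self) -> float:
        """p' = p_I' + p_E', the total horizontal error rate."""
        return self.p_ingress_horizontal + self.p_egress_horizontal

    @classmethod
    def from_temperature(cls, tau: float) -> "FeatureParams":
        """Symmetric pure-horizontal parameters realizing temperature tau.

        Uses q = 1 and p_I' = p_E' = tau / (2 (1 + tau)), the analytically
        solved special case of undirected horizontal errors, so the
        stationary theory is exact for the resulting dynamics and the
        stationary frequency is 1/2.
        """
        if tau < 0.0:
            raise ValueError(f"temperature must be >= 0, got {tau!r}")
        e = tau / (2.0 * (1.0 + tau))
        return cls(p_ingress_horizontal=e, p_egress_horizontal=e,
                   q_horizontal_rate=1.0)
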