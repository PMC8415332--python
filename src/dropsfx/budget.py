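"""Sample-consumption arithmetic and Poisson crystal-occupancy modeling.

Drop delivery consumes volume = drop volume × repetition rate (an 80 µm
spherical drop is ~268 pl; at "about 250 pl" per drop and 60 Hz that is
0.9 µl min⁻¹). The number of crystals the beam probes per drop is Poisson
with mean λ = concentration × probed volume, where the probed volume is
only an interaction fraction of the drop (the X-ray focus is far smaller
than the drop). That single model links slurry concentration to hit rate
(P(hit) = 1 − e^−λ), to multi-crystal pattern frequency, and — inverted —
to a concentration estimate from an observed hit rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def drop_volume_from_diameter(diameter_um: float) -> float:
    """Spherical drop volume in pl for a diameter in µm (π/6·d³)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi / 6.0 * diameter_um ** 3 * 1e-3   # µm³ -> pl


def volumetric_rate(drop_volume_pl: float, frequency_hz: float) -> float:
    """Volumetric consumption in µl min⁻¹ at a given dispense frequency."""
    if drop_volume_pl < 0 or frequency_hz < 0:
        raise ValueError("inputs must be non-negative")
    return drop_volume_pl * frequency_hz * 60.0 / 1e6


def hit_probability(concentration_per_nl: float, probed_volume_nl: float) -> float:
    """P(≥1 crystal in the probed volume) = 1 − e^−λ, λ = c·V."""
    if concentration_per_nl < 0 or probed_volume_nl < 0:
        raise ValueError("inputs must be non-negative")
    lam = concentration_per_nl * probed_volume_nl
    return -math.expm1(-lam)


def multi_crystal_probability(concentration_per_nl: float,
                              probed_volume_nl: float) -> float:
    """P(≥2 crystals | ≥1) under the same Poisson occupancy model."""
    if concentration_per_nl < 0 or probed_volume_nl < 0:
        raise ValueError("inputs must be non-negative")
    lam = concentration_per_nl * probed_volume_nl
    p_ge1 = -math.expm1(-lam)
    if p_ge1 == 0.0:
        return 0.0
    p_ge2 = p_ge1 - lam * math.exp(-lam)
    return p_ge2 / p_ge1


def estimate_concentration(observed_hit_rate_pct: float,
                           probed_volume_nl: float) -> float:
    """Invert the Poisson hit model: c = −ln(1 − rate/100) / V (crystals/nl).

    Only defined for rates strictly between 0 and 100% (a 100% hit rate is
    consistent with any sufficiently high concentration).
    """
    if not 0.0 < observed_hit_rate_pct < 100.0:
        raise ValueError("hit rate must lie strictly between 0 and 100%")
    if probed_volume_nl <= 0:
        raise ValueError("probed volume must be positive")
    return -math.log1p(-observed_hit_rate_pct / 100.0) / probed_volume_nl


def estimate_concentration_with_misses(observed_hit_rate_pct: float,
                                       probed_volume_nl: float,
                                       miss_probability: float) -> float:
    """Concentration estimate when a fraction of drops misses the beam.

    The observed hit rate is (1 − p_miss)·(1 − e^−λ); dividing out the miss
    factor before inverting.
    """
    if not 0.0 <= miss_probability < 1.0:
        raise ValueError("miss_probability must lie in [0, 1)")
    corrected = observed_hit_rate_pct / (1.0 - miss_probability)
    return estimate_concentration(corrected, probed_volume_nl)


@dataclass(frozen=True)
class ConsumptionModel:
    """Drop delivery consumption + occupancy report.

    ``interaction_fraction`` (fraction of the drop volume the beam probes)
    has no principled default — it depends on focus size and drop overlap —
    and must be supplied.
    """

    drop_diameter_um: float
    repetition_rate_hz: float
    concentration_per_nl: float
    interaction_fraction: float

    def __post_init__(self) -> None:
        if self.drop_diameter_um <= 0:
            raise ValueError("drop_diameter_um must be > 0")
        if self.repetition_rate_hz < 0 or self.concentration_per_nl < 0:
            raise ValueError("rate and concentration must be >= 0")
        if not 0.0 < self.interaction_fraction <= 1.0:
            raise ValueError("interaction_fraction must lie in (0, 1]")

    @property
    def drop_volume_pl(self) -> float:
        return drop_volume_from_diameter(self.drop_diameter_um)

    @property
    def probed_volume_nl(self) -> float:
        return self.drop_volume_pl * 1e-3 * self.interaction_fraction

    @property
    def lam(self) -> float:
        """Mean crystals per probed volume."""
        return self.concentration_per_nl * self.probed_volume_nl

    def report(self) -> dict:
        """JSON-ready consumption/occupancy summary."""
        return {
            "drop_volume_pl": self.drop_volume_pl,
            "rate_ul_per_min": volumetric_rate(self.drop_volume_pl,
                                               self.repetition_rate_hz),
            "lambda": self.lam,
            "p_hit": hit_probability(self.concentration_per_nl,
                                     self.probed_volume_nl),
            "p_multi_given_hit": multi_crystal_probability(
                self.concentration_per_nl, self.probed_volume_nl),
            "estimated_concentration_per_nl": self.concentration_per_nl,
        }
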