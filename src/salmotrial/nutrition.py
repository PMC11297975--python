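"""Deterministic nutrition calculators: growth, condition, digestibility, FAs.

Growth is summarised by the thermal growth coefficient (TGC, on degree-days)
and the specific growth rate (SGR, % per day); body shape by Fulton's
condition factor; organ size by organosomatic indices (% of body weight).
Apparent digestibility uses the inert-marker (yttrium oxide) method, and
fatty-acid quantification follows the FAME internal-standard scheme with
tridecanoic acid (13:0) and a per-acid response factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "GrowthRecord",
    "DigestibilityInput",
    "ChromQuant",
    "thermal_growth_coefficient",
    "specific_growth_rate",
    "fulton_condition",
    "organosomatic_index",
    "apparent_digestibility",
    "fa_mass",
    "fa_concentration",
    "digestible_content",
]


@dataclass(frozen=True)
class GrowthRecord:
    """Weights (g) bracketing a feeding period of ``days`` at ``mean_temp`` degC."""

    bw0: float
    bw1: float
    days: int
    mean_temp: float

    def __post_init__(self) -> None:
        if self.bw0 <= 0 or self.bw1 <= 0:
            raise ValueError("body weights must be > 0")
        if self.days < 1:
            raise ValueError("days must be >= 1")

    @property
    def degree_days(self) -> float:
        """ddg = feeding days x mean water temperature (degC)."""
        return self.days * self.mean_temp


@dataclass(frozen=True)
class DigestibilityInput:
    """Marker and nutrient fractions (% of DM) in feed and faeces."""

    marker_feed: float
    marker_faeces: float
    nutrient_feed: float
    nutrient_faeces: float

    def __post_init__(self) -> None:
        if self.marker_feed <= 0 or self.marker_faeces <= 0:
            raise ValueError("marker fractions must be > 0")
        if self.nutrient_feed <= 0:
            raise ValueError("feed nutrient fraction must be > 0")
        if self.nutrient_faeces < 0:
            raise ValueError("faeces nutrient fraction must be >= 0")
        if self.marker_faeces < self.marker_feed:
            warnings.warn(
                "marker is less concentrated in faeces than in feed; the inert "
                "marker normally concentrates as nutrients are absorbed",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ChromQuant:
    """Chromatographic peak areas for one fatty acid and the 13:0 standard.

    ``is_mass`` is the added internal-standard mass in mg (0.25 mg per 500 mg
    sample in the reference protocol); ``rf`` the response factor.
    """

    area_fa: float
    area_is: float
    rf: float
    is_mass: float
    sample_mass: float

    def __post_init__(self) -> None:
        if self.area_fa < 0:
            raise ValueError("area_fa must be >= 0")
        if self.area_is <= 0:
            raise ValueError("area_is must be > 0")
        if self.rf <= 0 or self.is_mass <= 0 or self.sample_mass <= 0:
            raise ValueError("rf, is_mass and sample_mass must be > 0")


def thermal_growth_coefficient(rec: GrowthRecord) -> float:
    """TGC = 1000 * (BW1^(1/3) - BW0^(1/3)) / degree-days."""
    ddg = rec.degree_days
    if ddg <= 0:
        raise ValueError(f"degree-days must be > 0, got {ddg}")
    return 1000.0 * (rec.bw1 ** (1.0 / 3.0) - rec.bw0 ** (1.0 / 3.0)) / ddg


def specific_growth_rate(rec: GrowthRecord, printed_variant: bool = False) -> float:
    """SGR in % per day: 100 * (ln BW1 - ln BW0) / days.

    ``printed_variant=True`` evaluates the typographic ratio-of-logs form
    100 * (ln BW1 / ln BW0) / days sometimes seen in print; it is kept only
    for comparison and is not the standard definition.
    """
    if printed_variant:
        return 100.0 * (math.log(rec.bw1) / math.log(rec.bw0)) / rec.days
    return 100.0 * (math.log(rec.bw1) - math.log(rec.bw0)) / rec.days


def fulton_condition(fbw: float, fl: float) -> float:
    """Fulton's condition factor K = 100 * FBW / FL^3 (g, cm)."""
    if fbw <= 0 or fl <= 0:
        raise ValueError("final body weight and fork length must be > 0")
    return 100.0 * fbw / fl**3


def organosomatic_index(organ: float, body: float) -> float:
    """OSI = 100 * organ weight / body weight, %."""
    if body <= 0:
        raise ValueError("body weight must be > 0")
    if organ < 0:
        raise ValueError("organ weight must be >= 0")
    return 100.0 * organ / body


def apparent_digestibility(d: DigestibilityInput) -> float:
    """Inert-marker apparent digestibility, %.

    AD = 100 - 100 * (M_feed / M_faeces) * (N_faeces / N_feed), the standard
    marker-ratio form: the marker concentrates in faeces exactly as much as
    nutrients disappear.
    """
    return 100.0 - 100.0 * (d.marker_feed / d.marker_faeces) * (
        d.nutrient_faeces / d.nutrient_feed
    )


def fa_mass(q: ChromQuant) -> float:
    """Fatty-acid mass (mg) = (area_FA / area_13:0) * RF * mass_13:0."""
    return (q.area_fa / q.area_is) * q.rf * q.is_mass


def fa_concentration(q: ChromQuant) -> float:
    """Fatty-acid concentration, mg per g of weighed sample."""
    return fa_mass(q) / q.sample_mass


def digestible_content(diet_conc: float, ad: float) -> float:
    """Digestible nutrient content in the diet: concentration x AD / 100."""
    if diet_conc < 0:
        raise ValueError("diet concentration must be >= 0")
    if ad > 100.0:
        raise ValueError("apparent digestibility cannot exceed 100 %")
    return diet_conc * ad / 100.0
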