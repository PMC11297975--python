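"""Seeded generators emulating the pen trial's statistical structure.

Every generator is a pure function of its configuration and seed: the same
inputs give bit-identical outputs, and no process-global random state is
touched.  Defaults mirror the reference trial layout — two size classes
crossed with rapeseed-oil levels {0, 5, 9, 14, 19, 24} % (twelve pens, one
per cell), twelve scored fish per pen, and 0.1 % yttrium oxide marker in
the feed.

* :func:`gen_pen_responses` draws Gaussian pen-level responses under any of
  the five mean-structure hypotheses (m1-m5).
* :func:`gen_histology_scores` draws per-fish ordinal scores from a
  proportional-odds model.
* :func:`gen_digestibility_trial` constructs feed/faeces compositions whose
  marker arithmetic recovers chosen true digestibilities exactly (plus
  optional multiplicative lognormal noise).
* :func:`gen_dose_response` tabulates monotone dose-response curves (linear
  or decreasing-logistic) usable as stand-ins for an external choline curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .nutrition import DigestibilityInput
from .ordinal import ScoreTable
from .steatosis import DoseResponseCurve
from .trial_data import OIL_LEVELS, SIZE_CLASSES, PenRecord, PenTable

import pandas as pd

__all__ = [
    "SimConfig",
    "gen_pen_responses",
    "gen_histology_scores",
    "gen_digestibility_trial",
    "gen_dose_response",
]


@dataclass(frozen=True)
class SimConfig:
    """Pen-level response simulation settings.

    Coefficients outside the chosen model's mean structure are ignored.
    ``sigma=0`` produces exact cell means.
    """

    model_id: str = "m1"
    beta0: float = 0.0
    beta_size: float = 0.0
    beta_oil: float = 0.0
    beta_interaction: float = 0.0
    sigma: float = 1.0
    oil_levels: tuple[float, ...] = OIL_LEVELS
    sizes: tuple[int, ...] = SIZE_CLASSES
    seed: int = 0
    variable: str = "response"

    def __post_init__(self) -> None:
        if self.model_id not in ("m1", "m2", "m3", "m4", "m5"):
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(set(self.oil_levels)) != len(self.oil_levels):
            raise ValueError("oil levels must be distinct")

    def mean(self, size: float, oil: float) -> float:
        mu = self.beta0
        if self.model_id in ("m3", "m4", "m5"):
            mu += self.beta_size * size
        if self.model_id in ("m2", "m4", "m5"):
            mu += self.beta_oil * oil
        if self.model_id == "m5":
            mu += self.beta_interaction * size * oil
        return mu


def gen_pen_responses(cfg: SimConfig) -> PenTable:
    """One Gaussian response per (size, oil) cell under the chosen model."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for size in cfg.sizes:
        for oil in cfg.oil_levels:
            value = cfg.mean(size, oil) + cfg.sigma * rng.standard_normal()
            records.append(
                PenRecord(
                    pen_id=f"S{size}-{oil:g}",
                    size=size,
                    rapeseed_oil=float(oil),
                    responses={cfg.variable: float(value)},
                )
            )
    return PenTable(records)


def gen_histology_scores(
    cutpoints: Sequence[float],
    beta_size: float = 0.0,
    beta_oil: float = 0.0,
    fish_per_pen: int = 12,
    oil_levels: Sequence[float] = OIL_LEVELS,
    sizes: Sequence[int] = SIZE_CLASSES,
    seed: int = 0,
    endpoint: str = "steatosis_PI",
) -> ScoreTable:
    """Multinomial per-pen score counts under a proportional-odds model.

    ``cutpoints`` are the K-1 increasing thresholds zeta_k; category
    probabilities at covariate value x are differences of
    ``expit(zeta_k - x beta)``.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.ndim != 1 or len(cutpoints) < 1:
        raise ValueError("need at least one cutpoint")
    if not np.all(np.diff(cutpoints) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    if fish_per_pen < 1:
        raise ValueError("fish_per_pen must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_cat = len(cutpoints) + 1
    for size in sizes:
        for oil in oil_levels:
            xb = beta_size * size + beta_oil * oil
            cum = np.concatenate([[0.0], expit(cutpoints - xb), [1.0]])
            probs = np.diff(cum)
            counts = rng.multinomial(fish_per_pen, probs)
            for score, count in enumerate(counts):
                rows.append(
                    {"size": size, "rapeseed_oil": oil, "score": score, "count": int(count)}
                )
    return ScoreTable(pd.DataFrame(rows), endpoint=endpoint)


def gen_digestibility_trial(
    true_ad: Mapping[str, float],
    nutrient_feed: Mapping[str, float] | None = None,
    marker_feed: float = 0.1,
    concentration_factor: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, DigestibilityInput]:
    """Feed/faeces compositions consistent with chosen true digestibilities.

    The faeces marker is ``marker_feed * concentration_factor`` (the factor
    by which indigestible matter concentrates); each nutrient's faeces
    fraction is solved from the marker-ratio digestibility formula so that
    noise-free recovery is exact.  ``noise_sd > 0`` applies multiplicative
    lognormal noise exp(noise_sd * z) to the faeces nutrient fraction.
    """
    if marker_feed <= 0:
        raise ValueError("marker_feed must be > 0")
    if concentration_factor <= 0:
        raise ValueError("concentration_factor must be > 0")
    nutrient_feed = dict(nutrient_feed or {})
    rng = np.random.default_rng(seed)
    out = {}
    for nutrient, ad in true_ad.items():
        if ad > 100.0:
            raise ValueError(f"true digestibility for {nutrient!r} exceeds 100 %")
        feed_frac = nutrient_feed.get(nutrient, 30.0)
        faeces = (1.0 - ad / 100.0) * feed_frac * concentration_factor
        if faeces < 0:
            raise ValueError(
                f"configuration yields negative faeces fraction for {nutrient!r}"
            )
        if noise_sd > 0:
            faeces *= float(np.exp(noise_sd * rng.standard_normal()))
        out[nutrient] = DigestibilityInput(
            marker_feed=marker_feed,
            marker_faeces=marker_feed * concentration_factor,
            nutrient_feed=feed_frac,
            nutrient_faeces=faeces,
        )
    return out


def gen_dose_response(
    family: str = "linear",
    *,
    dose_range: tuple[float, float] = (0.0, 4000.0),
    n_points: int = 401,
    score0: float = 4.5,
    slope: float = -1.0 / 1000.0,
    upper: float = 4.5,
    lower: float = 0.5,
    midpoint: float = 2000.0,
    scale: float = 500.0,
) -> DoseResponseCurve:
    """Tabulate a synthetic monotone dose-response curve.

    ``linear``: score(d) = score0 + slope * d (slope must be <= 0).
    ``logistic``: score(d) = lower + (upper - lower) * expit((midpoint - d)/scale),
    decreasing from ``upper`` toward ``lower``.
    """
    d0, d1 = dose_range
    if d1 <= d0:
        raise ValueError("dose_range must be increasing")
    doses = np.linspace(d0, d1, n_points)
    if family == "linear":
        if slope > 0:
            raise ValueError("linear family needs slope <= 0 (non-increasing scores)")
        scores = score0 + slope * doses
    elif family == "logistic":
        if upper <= lower or scale <= 0:
            raise ValueError("logistic family needs upper > lower and scale > 0")
        scores = lower + (upper - lower) * expit((midpoint - doses) / scale)
    else:
        raise ValueError(f"unknown dose-response family {family!r}")
    return DoseResponseCurve(doses=doses, scores=scores)
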