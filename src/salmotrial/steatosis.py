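"""Steatosis score lines and the choline-requirement indication mapping.

Mean steatosis score per size class is summarised by a first-degree
regression on dietary rapeseed-oil level (% of diet).  A shift in score
between two feeding conditions is then mapped onto an *indicative* shift in
dietary choline requirement by inverting an externally supplied monotone
dose-response curve (choline mg/kg -> expected steatosis score): the dose
difference between the two scores on that curve is the indicated
requirement shift.  All such outputs are flagged as indications of
magnitude, never as requirement estimates — the mapping borrows a curve
estimated under different experimental conditions.

The trial's published per-size regression lines are available as
:data:`SMALL_FISH_LINE` and :data:`LARGE_FISH_LINE`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreLine",
    "DoseResponseCurve",
    "RequirementIndication",
    "ExtrapolationError",
    "SMALL_FISH_LINE",
    "LARGE_FISH_LINE",
    "fit_score_line",
    "score_at",
    "score_shift",
    "indicate_requirement_shift",
    "round1",
]


class ExtrapolationError(ValueError):
    """A queried score or dose lies outside the curve's tabulated range."""


@dataclass(frozen=True)
class ScoreLine:
    """First-degree fit of mean steatosis score on rapeseed-oil level."""

    size: int  # 0 = small, 1 = large
    slope: float  # score units per % oil
    intercept: float  # score units at 0 % oil


#: Published per-size regression lines of mean steatosis score on oil level.
SMALL_FISH_LINE = ScoreLine(size=0, slope=0.0532, intercept=3.1111)
LARGE_FISH_LINE = ScoreLine(size=1, slope=0.0699, intercept=2.3452)


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (presentation rounding)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def fit_score_line(
    oil_levels: Sequence[float],
    mean_scores: Sequence[float],
    size: int = 0,
) -> ScoreLine:
    """Ordinary least squares line of mean score on oil level."""
    x = np.asarray(oil_levels, dtype=float)
    y = np.asarray(mean_scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("oil_levels and mean_scores must have equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct oil levels to fit a line")
    slope, intercept = np.polyfit(x, y, deg=1)
    return ScoreLine(size=size, slope=float(slope), intercept=float(intercept))


def score_at(line: ScoreLine, oil: float) -> float:
    """Predicted mean score at an oil level (unrounded)."""
    return line.intercept + line.slope * oil


def score_shift(line: ScoreLine, oil0: float, oil1: float) -> float:
    """Predicted score change between two oil levels (unrounded)."""
    return line.slope * (oil1 - oil0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Tabulated monotone mapping from choline dose (mg/kg) to expected score.

    Scores must be non-increasing in dose (more choline, less steatosis).
    Inversion interpolates linearly between the tabulated nodes and refuses
    to extrapolate beyond them.
    """

    doses: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if doses.ndim != 1 or doses.shape != scores.shape or len(doses) < 2:
            raise ValueError("need matching 1-D dose and score arrays, length >= 2")
        if not np.all(np.diff(doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing in dose")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseCurve":
        """Read a curve from CSV with columns ``dose_mg_per_kg``, ``score``."""
        frame = pd.read_csv(path)
        missing = {"dose_mg_per_kg", "score"} - set(frame.columns)
        if missing:
            raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
        frame = frame.sort_values("dose_mg_per_kg")
        return cls(frame["dose_mg_per_kg"].to_numpy(), frame["score"].to_numpy())

    def score_at_dose(self, dose: float) -> float:
        if not self.doses[0] <= dose <= self.doses[-1]:
            raise ExtrapolationError(
                f"dose {dose} outside tabulated range "
                f"[{self.doses[0]}, {self.doses[-1]}] mg/kg"
            )
        return float(np.interp(dose, self.doses, self.scores))

    def dose_at_score(self, score: float) -> float:
        """Monotone inverse by linear interpolation between nodes.

        On a flat segment (several doses sharing one score) the lowest dose
        of the segment is returned.
        """
        smin, smax = float(self.scores[-1]), float(self.scores[0])
        if not smin <= score <= smax:
            raise ExtrapolationError(
                f"score {score} outside curve range [{smin}, {smax}]"
            )
        # scores reversed are non-decreasing in reversed doses
        rev_scores = self.scores[::-1]
        rev_doses = self.doses[::-1]
        j = int(np.searchsorted(rev_scores, score, side="left"))
        if rev_scores[j] == score:
            # exact hit; take the lowest dose attaining this score
            while j + 1 < len(rev_scores) and rev_scores[j + 1] == score:
                j += 1
            return float(rev_doses[j])
        s0, s1 = rev_scores[j - 1], rev_scores[j]
        d0, d1 = rev_doses[j - 1], rev_doses[j]
        frac = (score - s0) / (s1 - s0)
        return float(d0 + frac * (d1 - d0))


@dataclass(frozen=True)
class RequirementIndication:
    """Indicated (not estimated) shift in choline requirement, mg/kg.

    ``shift_mg_per_kg`` = dose(score_to) - dose(score_from) on the supplied
    curve; the sign gives the direction of the requirement shift.
    """

    score_from: float
    score_to: float
    dose_from: float
    dose_to: float
    shift_mg_per_kg: float
    is_indication: bool = True


def indicate_requirement_shift(
    curve: DoseResponseCurve, score_a: float, score_b: float
) -> RequirementIndication:
    """Map a steatosis score shift onto an indicative requirement shift.

    Both scores are read off the curve at their own positions (no fixed
    anchor); scores outside the curve's range raise
    :class:`ExtrapolationError` rather than extrapolating silently.
    """
    dose_a = curve.dose_at_score(score_a)
    dose_b = curve.dose_at_score(score_b)
    return RequirementIndication(
        score_from=score_a,
        score_to=score_b,
        dose_from=dose_a,
        dose_to=dose_b,
        shift_mg_per_kg=dose_b - dose_a,
    )
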