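"""Proportional-odds ordinal regression of histology score distributions.

Histological endpoints (enterocyte steatosis in the pyloric intestine,
submucosal enteritis in the distal intestine) are scored per fish on an
ordinal 0-4 scale (0 normal; 1-4 mild, moderate, marked, severe).  The
effect of fish size and dietary rapeseed-oil level on the score
distribution is modelled with the proportional-odds (cumulative logit)
model

    logit P(Y <= k) = zeta_k - beta_size * Size - beta_oil * RapeOil,

so a positive coefficient shifts mass toward higher (worse) scores and
``exp(beta)`` is the cumulative odds ratio per unit of the covariate.  Fish
are treated as independent observations (pen clustering is ignored, a known
limitation of the approach).

The likelihood is maximised via :class:`statsmodels` ``OrderedModel`` with a
logit link, which uses the same ``zeta_k - x beta`` sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "ScoreTable",
    "OrdinalFit",
    "NonConvergenceError",
    "DegenerateScoresError",
    "fit_proportional_odds",
    "wald_p",
    "odds_ratio",
    "predicted_category_probs",
]

#: Steatosis severity categories and the affected-tissue proportions they encode.
STEATOSIS_SEVERITY = {
    0: "Normal (<= 10%)",
    1: "Mild (10-25%)",
    2: "Moderate (25-50%)",
    3: "Marked (>= 50%)",
    4: "Severe (>= 75%)",
}

_ENDPOINTS = ("steatosis_PI", "enteritis_DI")


class NonConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge (e.g. complete separation)."""


class DegenerateScoresError(ValueError):
    """Score table cannot support an ordinal fit (fewer than 2 categories)."""


@dataclass
class ScoreTable:
    """Counts of ordinal scores per (size, rapeseed_oil) group.

    ``counts`` has columns ``size``, ``rapeseed_oil``, ``score``, ``count``.
    """

    counts: pd.DataFrame
    endpoint: str = "steatosis_PI"

    def __post_init__(self) -> None:
        if self.endpoint not in _ENDPOINTS:
            raise ValueError(f"endpoint must be one of {_ENDPOINTS}")
        required = {"size", "rapeseed_oil", "score", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("score counts must be >= 0")
        if len(self.populated_categories()) < 2:
            raise DegenerateScoresError(
                "need at least 2 populated score categories overall"
            )

    def populated_categories(self) -> list[int]:
        present = self.counts.loc[self.counts["count"] > 0, "score"]
        return sorted(int(s) for s in present.unique())

    def to_observations(self) -> pd.DataFrame:
        """Expand counts into one row per fish."""
        rows = self.counts.loc[
            self.counts["count"] > 0, ["size", "rapeseed_oil", "score", "count"]
        ]
        return rows.loc[
            rows.index.repeat(rows["count"].astype(int))
        ].drop(columns="count").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str = "steatosis_PI") -> "ScoreTable":
        return cls(pd.read_csv(path), endpoint=endpoint)

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index=False)


@dataclass(frozen=True)
class OrdinalFit:
    """Converged proportional-odds fit.

    ``cutpoints`` are the K-1 strictly increasing thresholds zeta_k on the
    latent logit scale; ``categories`` are the (possibly merged) original
    score labels in order.
    """

    cutpoints: np.ndarray
    coef: dict[str, float]
    se: dict[str, float]
    loglike: float
    converged: bool
    categories: tuple[int, ...]
    n_obs: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError(f"cutpoints must be strictly increasing: {self.cutpoints}")


def fit_proportional_odds(
    scores: ScoreTable,
    terms: Sequence[str] = ("size", "rapeseed_oil"),
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of a score table.

    Unpopulated categories interior to the observed range are merged into
    the next lower populated category with a warning.  Complete separation
    or other optimisation failure raises :class:`NonConvergenceError`.
    """
    obs = scores.to_observations()
    terms = list(terms)
    for term in terms:
        if obs[term].nunique() < 2:
            raise DegenerateScoresError(
                f"covariate {term!r} does not vary across observed fish"
            )

    populated = scores.populated_categories()
    lo, hi = populated[0], populated[-1]
    interior_empty = [
        k for k in range(lo, hi + 1) if k not in populated
    ]
    if interior_empty:
        warnings.warn(
            f"empty interior score categories merged downward: {interior_empty}",
            stacklevel=2,
        )
    # Map scores onto consecutive codes over populated categories.
    code = {cat: i for i, cat in enumerate(populated)}
    endog = pd.Categorical(
        obs["score"].map(code), categories=range(len(populated)), ordered=True
    )
    exog = obs[terms].astype(float)

    model = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimizer chatter only
        try:
            fit = model.fit(method="bfgs", maxiter=500, disp=False)
        except Exception as exc:
            raise NonConvergenceError(f"ordinal fit failed: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    if not converged or not np.all(np.isfinite(bse[: len(terms)])):
        raise NonConvergenceError(
            "ordinal fit did not converge (possible complete separation); "
            f"coefficients {dict(zip(terms, params[: len(terms)]))}"
        )
    cutpoints = model.transform_threshold_params(params)[1:-1]
    return OrdinalFit(
        cutpoints=np.asarray(cutpoints, dtype=float),
        coef={t: float(params[i]) for i, t in enumerate(terms)},
        se={t: float(bse[i]) for i, t in enumerate(terms)},
        loglike=float(fit.llf),
        converged=converged,
        categories=tuple(populated),
        n_obs=len(obs),
    )


def wald_p(fit: OrdinalFit, term: str) -> float:
    """Two-sided normal-approximation p-value for one coefficient."""
    if not fit.converged:
        raise NonConvergenceError("cannot test a non-converged fit")
    z = fit.coef[term] / fit.se[term]
    return float(2.0 * norm.sf(abs(z)))


def odds_ratio(fit: OrdinalFit, term: str) -> float:
    """Cumulative odds ratio per unit increase of a covariate."""
    return float(np.exp(fit.coef[term]))


def predicted_category_probs(
    fit: OrdinalFit, size: float, rapeseed_oil: float
) -> np.ndarray:
    """Predicted probability of each (merged) category at a covariate value.

    Differences of inverse-logit cumulative probabilities; sums to 1.
    """
    xb = fit.coef.get("size", 0.0) * size + fit.coef.get("rapeseed_oil", 0.0) * rapeseed_oil
    cum = expit(fit.cutpoints - xb)
    cum = np.concatenate([[0.0], cum, [1.0]])
    return np.diff(cum)
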