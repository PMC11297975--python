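"""Bayesian comparison of five linear hypotheses for pen-level responses.

For each response variable the pen means are modelled as
``Y_i ~ N(mu_k(x_i), sigma^2)`` with five nested mean structures:

* ``m1``: intercept only (no effects),
* ``m2``: + rapeseed-oil level,
* ``m3``: + size class,
* ``m4``: + size + oil,
* ``m5``: + size + oil + size x oil interaction.

Coefficient priors are independent N(0, v) (default v = 1000) with a fully
flat (improper) prior on the intercept; the residual precision tau = 1/sigma^2
carries a gamma(shape, rate) prior (default shape 1, rate 5e-5).  Conditional
on tau the marginal likelihood is available in closed form (the flat intercept
is integrated against Lebesgue measure); the tau dimension is then integrated
by a deterministic mode-centered Gauss-Hermite quadrature over log tau, so the
whole computation is exact up to quadrature error and bit-reproducible.

Posterior model probabilities follow by renormalising the marginal
likelihoods under a uniform model prior; the Bayes factor between the two
most probable models (BF12) is categorised on the conventional evidence
scale: [1, 3.2) negligible, [3.2, 10) substantial, [10, 100) strong,
[100, inf) decisive.

Model fit of the selected model is screened by a one-sample
Kolmogorov-Smirnov test of the standardized residuals against the standard
normal distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .trial_data import PenTable

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "SelectionResult",
    "DiagnosticResult",
    "PosteriorLine",
    "MODELS",
    "MODEL_IDS",
    "DegenerateDesignError",
    "NumericalDegeneracyError",
    "design_matrix",
    "log_marginal_fixed_precision",
    "log_marginal",
    "posterior_model_probs",
    "bayes_factor",
    "evidence_category",
    "select_model",
    "posterior_line",
    "ks_residual_check",
    "ks_standard_normal",
    "intervals_overlap",
]


class DegenerateDesignError(ValueError):
    """A model term is constant across pens, so its effect is unidentifiable."""


class NumericalDegeneracyError(ArithmeticError):
    """The prior-integration linear algebra is singular or non-finite."""


# Term names in fixed column order: intercept, size, oil, interaction.
_TERM_ORDER = ("intercept", "size", "rapeseed_oil", "size:rapeseed_oil")


@dataclass(frozen=True)
class ModelSpec:
    """One of the five mean-structure hypotheses."""

    model_id: str

    _TERMS = {
        "m1": ("intercept",),
        "m2": ("intercept", "rapeseed_oil"),
        "m3": ("intercept", "size"),
        "m4": ("intercept", "size", "rapeseed_oil"),
        "m5": ("intercept", "size", "rapeseed_oil", "size:rapeseed_oil"),
    }

    def __post_init__(self) -> None:
        if self.model_id not in self._TERMS:
            raise ValueError(f"unknown model id {self.model_id!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in _TERM_ORDER if t in self._TERMS[self.model_id])


MODEL_IDS: tuple[str, ...] = ("m1", "m2", "m3", "m4", "m5")
MODELS: tuple[ModelSpec, ...] = tuple(ModelSpec(m) for m in MODEL_IDS)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for coefficients, residual precision, and model space.

    ``intercept_variance=None`` selects the completely flat improper
    intercept prior, handled analytically (not as a large finite variance).
    ``precision_shape``/``precision_rate`` parameterise the gamma prior on
    tau = 1/sigma^2.  ``quad_nodes`` sets the Gauss-Hermite node count of the
    log-tau quadrature.
    """

    fixed_effect_variance: float = 1000.0
    intercept_variance: float | None = None
    precision_shape: float = 1.0
    precision_rate: float = 5e-5
    model_prior: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    quad_nodes: int = 51

    def __post_init__(self) -> None:
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be > 0")
        if self.intercept_variance is not None and self.intercept_variance <= 0:
            raise ValueError("intercept_variance must be > 0 or None (flat)")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("precision prior shape and rate must be > 0")
        if len(self.model_prior) != len(MODEL_IDS):
            raise ValueError("model_prior must have one entry per model")
        if abs(sum(self.model_prior) - 1.0) > 1e-9 or min(self.model_prior) < 0:
            raise ValueError("model_prior must be a probability vector")
        if self.quad_nodes < 3:
            raise ValueError("quad_nodes must be >= 3")


@dataclass(frozen=True)
class DiagnosticResult:
    """KS screening of standardized residuals of a fitted model."""

    residuals: np.ndarray
    ks_statistic: float
    ks_p: float
    passed: bool


@dataclass(frozen=True)
class SelectionResult:
    """Full model-selection output for one response variable."""

    variable: str
    log_marginals: dict[str, float]
    probabilities: dict[str, float]
    best_model: str
    second_model: str
    bf12: float
    evidence: str
    diagnostics: DiagnosticResult


@dataclass(frozen=True)
class PosteriorLine:
    """Coefficient posterior summaries and credible prediction bands."""

    model_id: str
    coefficients: dict[str, dict[str, float]]  # term -> {mean, q2.5, q50, q97.5}
    points: list[tuple[float, float]]  # (size, oil) query points
    predicted_mean: np.ndarray
    lower: np.ndarray  # 2.5 %
    median: np.ndarray
    upper: np.ndarray  # 97.5 %


def design_matrix(
    table: PenTable, variable: str, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Response vector and covariate matrix for one model.

    Columns are ordered [intercept, size, rapeseed_oil, size x oil] restricted
    to the model's terms; oil stays in raw % units and size in {0, 1} (no
    centering or scaling).  Raises :class:`DegenerateDesignError` when a
    requested non-intercept term is constant across pens.
    """
    y = table.response_vector(variable)
    size, oil = table.covariates()
    cols = {
        "intercept": np.ones_like(y),
        "size": size,
        "rapeseed_oil": oil,
        "size:rapeseed_oil": size * oil,
    }
    X = np.column_stack([cols[t] for t in spec.terms])
    for j, term in enumerate(spec.terms):
        if term != "intercept" and np.ptp(X[:, j]) == 0.0:
            raise DegenerateDesignError(
                f"term {term!r} is constant across pens; {spec.model_id} "
                "is unidentifiable on this design"
            )
    return y, X


def _prior_variances(p: int, prior: PriorSpec) -> np.ndarray:
    """Per-column prior variances; np.inf marks the flat intercept."""
    v = np.full(p, prior.fixed_effect_variance)
    v[0] = np.inf if prior.intercept_variance is None else prior.intercept_variance
    return v


def log_marginal_fixed_precision(
    y: np.ndarray, X: np.ndarray, prior: PriorSpec, tau: float
) -> float:
    """Closed-form log of int N(y | X beta, tau^-1 I) p(beta) dbeta.

    The first column of ``X`` must be the intercept.  A flat intercept is
    integrated against Lebesgue measure exactly (the infinite-variance
    limit), which contributes a factor sqrt(2 pi / (n tau)) and projects the
    data onto deviations from the mean; Gaussian N(0, v) priors apply to the
    remaining coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n or n < p:
        raise ValueError(f"need rows(X) == len(y) >= cols(X); got {X.shape}, {len(y)}")
    if tau <= 0 or not math.isfinite(tau):
        raise ValueError(f"tau must be a positive finite precision, got {tau}")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first column of X must be the intercept (all ones)")

    # Canonical row order makes the floating-point reductions, and hence the
    # returned value, bit-identical under permutation of the observations.
    order = np.lexsort((y, *X.T[::-1]))
    y, X = y[order], X[order]

    flat = prior.intercept_variance is None
    if flat:
        # Integrate the intercept out first: centers y and the other columns.
        Z = X[:, 1:] - X[:, 1:].mean(axis=0)
        yc = y - y.mean()
        out = (
            0.5 * (n - 1) * math.log(tau / (2.0 * math.pi))
            - 0.5 * math.log(n)
            - 0.5 * tau * float(yc @ yc)
        )
        variances = np.full(Z.shape[1], prior.fixed_effect_variance)
    else:
        Z = X
        yc = y
        out = 0.5 * n * math.log(tau / (2.0 * math.pi)) - 0.5 * tau * float(yc @ yc)
        variances = _prior_variances(p, prior)

    q = Z.shape[1]
    if q:
        A = tau * (Z.T @ Z) + np.diag(1.0 / variances)
        b = tau * (Z.T @ yc)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                f"singular prior-integration matrix (shape {A.shape}): {exc}"
            ) from exc
        half = np.linalg.solve(L, b)
        out += (
            -0.5 * float(np.sum(np.log(variances)))
            - float(np.sum(np.log(np.diag(L))))
            + 0.5 * float(half @ half)
        )
    if not math.isfinite(out):
        raise NumericalDegeneracyError(f"non-finite fixed-precision marginal: {out}")
    return out


def _log_tau_joint(y: np.ndarray, X: np.ndarray, prior: PriorSpec):
    """h(t) = log m(e^t) + log p_gamma(e^t) + t, the log-tau integrand."""
    shape, rate = prior.precision_shape, prior.precision_rate
    lognorm = shape * math.log(rate) - special.gammaln(shape)

    def h(t: float) -> float:
        tau = math.exp(t)
        log_prior = lognorm + (shape - 1.0) * t - rate * tau
        # + t is the Jacobian of tau -> log tau.
        return log_marginal_fixed_precision(y, X, prior, tau) + log_prior + t

    return h


def _tau_mode_and_scale(h, lo: float = -40.0, hi: float = 40.0) -> tuple[float, float]:
    """Locate the mode of the log-tau integrand and its Laplace scale."""
    grid = np.linspace(lo, hi, 321)
    vals = np.array([h(t) for t in grid])
    t0 = float(grid[int(np.argmax(vals))])
    res = optimize.minimize_scalar(
        lambda t: -h(t),
        bounds=(t0 - 1.0, t0 + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t0 = float(res.x)
    d = 1e-4
    curv = (h(t0 + d) - 2.0 * h(t0) + h(t0 - d)) / d**2
    scale = 1.0 / math.sqrt(max(-curv, 1e-12))
    return t0, scale


def _tau_quadrature(
    y: np.ndarray, X: np.ndarray, prior: PriorSpec, nodes: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gauss-Hermite nodes over log tau.

    Returns ``(taus, log_weights, log_evidence)`` where the (normalised)
    weights are the posterior masses of the tau nodes and ``log_evidence`` is
    the log marginal likelihood integrated over tau.
    """
    h = _log_tau_joint(y, X, prior)
    t0, s = _tau_mode_and_scale(h)
    x, w = np.polynomial.hermite.hermgauss(nodes or prior.quad_nodes)
    t = t0 + math.sqrt(2.0) * s * x
    hv = np.array([h(ti) for ti in t])
    log_terms = hv + x**2 + np.log(w)
    log_evidence = math.log(math.sqrt(2.0) * s) + float(special.logsumexp(log_terms))
    if not math.isfinite(log_evidence):
        raise NumericalDegeneracyError(
            "non-finite tau quadrature; integrand range "
            f"[{np.min(hv)}, {np.max(hv)}]"
        )
    log_weights = log_terms - special.logsumexp(log_terms)
    return np.exp(t), log_weights, log_evidence


def log_marginal(y: np.ndarray, X: np.ndarray, prior: PriorSpec) -> float:
    """Log marginal likelihood with the residual precision integrated out.

    Deterministic for fixed inputs: the quadrature grid depends only on the
    integrand, never on a random source.
    """
    return _tau_quadrature(y, X, prior)[2]


def posterior_model_probs(
    lmls: Sequence[float], model_prior: Sequence[float] | None = None
) -> np.ndarray:
    """Renormalise log marginal likelihoods into model probabilities."""
    lmls = np.asarray(lmls, dtype=float)
    if not np.all(np.isfinite(lmls)):
        raise ValueError(f"non-finite log marginal likelihoods: {lmls}")
    if model_prior is None:
        model_prior = np.full(len(lmls), 1.0 / len(lmls))
    logp = lmls + np.log(np.asarray(model_prior, dtype=float))
    logp -= np.max(logp)  # max-subtraction for stability
    p = np.exp(logp)
    return p / p.sum()


def bayes_factor(lml_a: float, lml_b: float) -> float:
    """Bayes factor of model a over model b from log marginal likelihoods."""
    return math.exp(lml_a - lml_b)


_EVIDENCE_BINS = (
    (3.2, "Negligible"),
    (10.0, "Substantial"),
    (100.0, "Strong"),
    (math.inf, "Decisive"),
)


def evidence_category(bf: float) -> str:
    """Evidence label on the conventional Bayes-factor scale.

    Half-open bins [1, 3.2), [3.2, 10), [10, 100), [100, inf).  A Bayes
    factor below 1 is folded by its reciprocal (the evidence then favours the
    other model; the caller keeps track of direction).
    """
    if bf < 0 or not math.isfinite(bf) and bf != math.inf:
        raise ValueError(f"Bayes factor must be >= 0, got {bf}")
    folded = bf if bf >= 1.0 else (math.inf if bf == 0.0 else 1.0 / bf)
    for upper, label in _EVIDENCE_BINS:
        if folded < upper:
            return label
    return "Decisive"


def _ranked_models(probs: np.ndarray, tol: float = 1e-12) -> list[int]:
    """Model indices by decreasing probability; ties favour the simpler model."""
    rounded = np.round(probs / tol) * tol
    return sorted(range(len(probs)), key=lambda i: (-rounded[i], i))


def select_model(
    table: PenTable, variable: str, prior: PriorSpec | None = None
) -> SelectionResult:
    """Run the full selection chain for one response variable.

    design -> log marginal x5 -> posterior model probabilities -> BF12 ->
    evidence label -> KS residual diagnostics on the winning model.
    Deterministic for fixed input and prior.
    """
    prior = prior or PriorSpec()
    lmls: dict[str, float] = {}
    try:
        for spec in MODELS:
            y, X = design_matrix(table, variable, spec)
            lmls[spec.model_id] = log_marginal(y, X, prior)
        probs = posterior_model_probs(list(lmls.values()), prior.model_prior)
        order = _ranked_models(probs)
        best, second = MODEL_IDS[order[0]], MODEL_IDS[order[1]]
        bf12 = bayes_factor(lmls[best], lmls[second])
        diag = ks_residual_check(table, variable, ModelSpec(best), prior)
    except Exception as exc:
        exc.add_note(f"while selecting a model for variable {variable!r}")
        raise
    return SelectionResult(
        variable=variable,
        log_marginals=lmls,
        probabilities=dict(zip(MODEL_IDS, probs.tolist())),
        best_model=best,
        second_model=second,
        bf12=max(bf12, 1.0),
        evidence=evidence_category(bf12),
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# Coefficient posteriors, prediction bands, diagnostics


def _conditional_posterior(
    y: np.ndarray, X: np.ndarray, prior: PriorSpec, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior of all coefficients given tau.

    The flat intercept enters with zero prior precision, giving the
    ridge-type closed form mean (tau X'X + V^-1)^-1 tau X'y.
    """
    p = X.shape[1]
    v = _prior_variances(p, prior)
    prior_prec = np.where(np.isinf(v), 0.0, 1.0 / v)
    P = tau * (X.T @ X) + np.diag(prior_prec)
    cov = np.linalg.inv(P)
    mean = cov @ (tau * (X.T @ y))
    return mean, cov


def _mixture_quantile(
    means: np.ndarray, sds: np.ndarray, weights: np.ndarray, q: float
) -> float:
    """Quantile of a finite Gaussian mixture by bracketed root finding."""
    lo = float(np.min(means - 10.0 * sds))
    hi = float(np.max(means + 10.0 * sds))
    def cdf(x: float) -> float:
        return float(np.sum(weights * stats.norm.cdf((x - means) / sds))) - q
    return float(optimize.brentq(cdf, lo, hi, xtol=1e-10))


def posterior_line(
    table: PenTable,
    variable: str,
    spec: ModelSpec,
    prior: PriorSpec | None = None,
    points: Sequence[tuple[float, float]] | None = None,
) -> PosteriorLine:
    """Coefficient posterior and 95 % credible prediction band.

    The posterior is the mixture of the fixed-tau Gaussian conditionals over
    the tau quadrature weights.  The band covers the posterior mean response
    (no observation noise added), matching the credible-interval comparison
    rule: non-overlapping 95 % intervals at a point are read as a clear
    difference (see :func:`intervals_overlap`).
    """
    prior = prior or PriorSpec()
    if points is None:
        points = [(s, o) for s in (0.0, 1.0) for o in (0.0, 5.0, 9.0, 14.0, 19.0, 24.0)]
    for s, o in points:
        if s not in (0.0, 1.0) or not 0.0 <= o <= 100.0:
            raise ValueError(
                f"query point (size={s}, oil={o}) outside coding conventions "
                "(size in {0,1}, oil in [0,100] %)"
            )
    y, X = design_matrix(table, variable, spec)
    taus, log_w, _ = _tau_quadrature(y, X, prior)
    w = np.exp(log_w)

    cond = [_conditional_posterior(y, X, prior, t) for t in taus]
    means = np.array([m for m, _ in cond])  # (nodes, p)
    sds = np.array([np.sqrt(np.diag(c)) for _, c in cond])

    coefficients = {}
    for j, term in enumerate(spec.terms):
        coefficients[term] = {
            "mean": float(np.sum(w * means[:, j])),
            "q2.5": _mixture_quantile(means[:, j], sds[:, j], w, 0.025),
            "q50": _mixture_quantile(means[:, j], sds[:, j], w, 0.5),
            "q97.5": _mixture_quantile(means[:, j], sds[:, j], w, 0.975),
        }

    cols = {
        "intercept": lambda s, o: 1.0,
        "size": lambda s, o: s,
        "rapeseed_oil": lambda s, o: o,
        "size:rapeseed_oil": lambda s, o: s * o,
    }
    pred_mean = np.empty(len(points))
    lower = np.empty(len(points))
    median = np.empty(len(points))
    upper = np.empty(len(points))
    for i, (s, o) in enumerate(points):
        xq = np.array([cols[t](s, o) for t in spec.terms])
        m_j = means @ xq
        s_j = np.sqrt(np.array([float(xq @ c @ xq) for _, c in cond]))
        pred_mean[i] = float(np.sum(w * m_j))
        lower[i] = _mixture_quantile(m_j, s_j, w, 0.025)
        median[i] = _mixture_quantile(m_j, s_j, w, 0.5)
        upper[i] = _mixture_quantile(m_j, s_j, w, 0.975)
    return PosteriorLine(
        model_id=spec.model_id,
        coefficients=coefficients,
        points=[(float(s), float(o)) for s, o in points],
        predicted_mean=pred_mean,
        lower=lower,
        median=median,
        upper=upper,
    )


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Whether two credible intervals overlap (the comparison rule helper)."""
    (alo, ahi), (blo, bhi) = a, b
    return max(alo, blo) <= min(ahi, bhi)


def ks_standard_normal(residuals: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of residuals against N(0, 1).

    The p-value uses the asymptotic Kolmogorov distribution.
    """
    residuals = np.asarray(residuals, dtype=float)
    res = stats.kstest(residuals, "norm", mode="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_residual_check(
    table: PenTable,
    variable: str,
    spec: ModelSpec,
    prior: PriorSpec | None = None,
) -> DiagnosticResult:
    """KS screen of standardized residuals of one fitted model.

    Residuals are standardized by the posterior-mean coefficients and the
    posterior-mean residual SD (E[tau^-1/2] over the tau quadrature);
    ``passed`` is True when the asymptotic KS p-value exceeds 0.05.  Because
    location and scale are estimated from the same data, the screen is
    conservative: it under-rejects relative to its nominal level.
    """
    prior = prior or PriorSpec()
    y, X = design_matrix(table, variable, spec)
    if len(y) < 3:
        raise ValueError(f"need at least 3 observations for the KS check, got {len(y)}")
    taus, log_w, _ = _tau_quadrature(y, X, prior)
    w = np.exp(log_w)
    beta = np.zeros(X.shape[1])
    for t, wi in zip(taus, w):
        m, _ = _conditional_posterior(y, X, prior, t)
        beta += wi * m
    sigma = float(np.sum(w / np.sqrt(taus)))
    residuals = (y - X @ beta) / sigma
    stat, p = ks_standard_normal(residuals)
    return DiagnosticResult(
        residuals=residuals, ks_statistic=stat, ks_p=p, passed=bool(p > 0.05)
    )
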