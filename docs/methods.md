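# Methods

## Design and data model

The reference design is an unreplicated 2 × 6 factorial: two fish size
classes (coded 0 = small autumn smolt, 1 = large spring smolt) crossed with
six dietary rapeseed-oil levels (0, 5, 9, 14, 19, 24 % of diet), one sea pen
per cell.  The pen is the experimental unit for all Gaussian analyses; fish
nested in pens appear only in the ordinal histology model.  Pen tables are
plain CSV (comma, UTF-8, dot decimals, header row) with `size`,
`rapeseed_oil`, and one column per response.  The packaged fixtures store
the published summary tables cell-for-cell as printed (1–2 decimals);
no attempt is made to back-correct toward unrounded pen means, because the
printed values are the only in-package ground truth.  Range guards on the
per-pen organ/lipid table (PI lipid 62–129, mesenteric lipid 589–830, liver
lipid 27–55 g/kg) catch transcription errors.

## Bayesian model comparison

For each response the five mean structures m1–m5 (intercept; + oil; + size;
+ size + oil; + size + oil + interaction) are compared through exact
marginal likelihoods.  Covariates stay in raw units (oil in %, size in
{0, 1}); with the default N(0, 1000) slope priors this makes results
coding-dependent in the usual way, and matches the convention under which
the published coefficients are reported.

Conditional on the residual precision tau, the coefficient integral is
closed-form.  The flat intercept prior is handled analytically as the
improper (Lebesgue) limit rather than as a large finite variance: the
intercept direction integrates to `sqrt(2 pi / (n tau))` and projects the
data onto deviations from their mean, after which the remaining slopes are
integrated against their Gaussian priors via a Cholesky factorisation.
Under this convention the marginal likelihood of a single observation under
m1 is exactly 1.  The improper prior's arbitrary constant cancels in every
model comparison because all five models share the same intercept.

The precision prior is gamma(shape 1, rate 5e-5) on tau — the conventional
weakly-informative default for Gaussian latent models.  The tau dimension
is integrated by deterministic quadrature in t = log tau: a coarse grid
(321 points on [−40, 40]) followed by bounded scalar refinement locates the
mode of the log integrand, a finite-difference second derivative sets the
Laplace scale `s`, and 51 Gauss–Hermite nodes centred at the mode with
spacing `sqrt(2) s` evaluate the integral in log space (log-sum-exp).  The
node count is configurable; 51 vs 201 nodes agree to < 1e-6 log units on
the packaged data, and the whole computation is bit-reproducible for fixed
inputs (observation order is canonicalised before the floating-point
reductions, so permuting pens cannot change the value).

Posterior model probabilities renormalise the marginal likelihoods under a
uniform model prior with max-subtraction for stability.  BF12 is the Bayes
factor between the two most probable models, labelled Negligible /
Substantial / Strong / Decisive on the half-open bins [1, 3.2), [3.2, 10),
[10, 100), [100, ∞); a Bayes factor below 1 is folded by its reciprocal.
Ties in probability at 1e-12 resolve toward the simpler (lower-index)
model.  Coefficient posteriors and 95 % credible prediction bands come from
the same machinery: the posterior is the finite mixture of the fixed-tau
Gaussian conditionals weighted by the tau-quadrature masses, and mixture
quantiles are solved by bracketed root finding on the mixture CDF.  The
bands cover the posterior mean response (no observation noise), matching
the comparison rule that reads non-overlapping 95 % intervals as a clear
difference.

Two numerical consequences of the precision prior are worth knowing.
First, the gamma rate 5e-5 floors the posterior rate, so even noise-free
data leave a residual-SD scale of about `sqrt(rate)`; credible bands
therefore bottom out near 1e-2 width instead of collapsing to zero.
Second, best-model identity on the packaged table is insensitive to a
ten-fold change of the rate in either direction (a property test asserts
this).

### Residual screening

Standardized residuals of the selected model use the posterior-mean
coefficients and the posterior-mean residual SD `E[tau^-1/2]`, and are
tested against N(0, 1) with a one-sample Kolmogorov–Smirnov statistic whose
p-value comes from the asymptotic Kolmogorov distribution; `pass` means
p > 0.05.  Under its own null (residuals truly standard normal, n = 12) the
stage rejects at ≈ 0.04 for a nominal 0.05.  Through the full pipeline the
screen is strongly conservative — location and scale are estimated from the
same twelve observations, the classical Lilliefors effect — so it
under-rejects (measured rate ≈ 0 at n = 12) and should be read as a coarse
guard against gross misfit, not a calibrated test.

### Reproduction limits

On the packaged (printed, rounded) twelve-pen table the pipeline reproduces
the published best model for 7 of 8 variables and the published maximum
probability for OSIPI (0.975 vs 0.978).  For mesenteric lipid the published
winner m4 and the recomputed winner m1 sit a factor ≈ 1.1 apart in marginal
likelihood; for OSIDI and OSIMes the recomputed probabilities (0.999,
0.969) differ from the published 0.921 and 0.999.  A perturbation study —
redrawing every cell uniformly within ± half of its printed rounding unit —
never reaches the published statistics, so they evidently derive from
unrounded pen data that the printed table cannot recover (OSIDI is the
clearest case: values of 0.4–0.6 printed to one decimal quantise most of
the variance away, hardening the no-effect model).  The corresponding
assertions are kept at face value in the acceptance tests and fail
honestly; the `reproduce-paper` report shows both sets of numbers
side-by-side with absolute differences.  Published BF12 magnitudes are
reported but never asserted: they are the most prior-sensitive output.

## Ordinal histology model

Scores 0–4 per fish are modelled with the proportional-odds cumulative
logit `logit P(Y <= k) = zeta_k − beta_size Size − beta_oil RapeOil`, so
positive coefficients shift mass toward worse scores and `exp(beta)` is a
cumulative odds ratio.  The likelihood is maximised by statsmodels'
`OrderedModel` (logit link, BFGS), which uses the same sign convention;
standard errors come from the inverse observed information and Wald tests
from the normal approximation.  Unpopulated categories interior to the
observed score range are merged downward with a warning; complete
separation surfaces as a non-convergence error.  Fish are treated as
independent — pen clustering is ignored, as in the original analysis — so
p-values are anti-conservative to the (unquantified) extent that pens
induce correlation.  Size and oil can be fitted jointly (default) or
singly via the `terms` argument.

## Nutrition calculators

* TGC = 1000 (BW1^(1/3) − BW0^(1/3)) / ddg, with ddg = days × mean
  temperature (°C).
* SGR = 100 (ln BW1 − ln BW0) / days, the standard log-difference form.  A
  typographic variant that divides logs instead of subtracting them
  circulates in print; it is available behind `printed_variant=True` for
  comparison only.
* CF = 100 FBW / FL³ (g, cm); OSI = 100 organ / body (%).
* Apparent digestibility AD = 100 − 100 (M_feed/M_faeces)(N_faeces/N_feed),
  the standard inert-marker form: the marker concentrates in faeces exactly
  as much as nutrients disappear.  (A printed variant with the nutrient
  ratio inverted yields negative digestibilities for typical inputs and is
  not implemented.)
* FA (mg) = (area_FA / area_13:0) × RF × mass_13:0; concentration divides
  by the weighed sample mass.  Digestible content = diet concentration ×
  AD / 100.

## Score lines and requirement indications

Mean steatosis score per size class is regressed on oil level by OLS;
evaluation and shifts are exact, with half-away-from-zero rounding to one
decimal applied only at presentation (reproducing the published 3.1 / 2.3 /
0.8 / 1.7).  The published small-fish shift (1.2 over 0→24 %) is not
reproducible under this rounding (0.0532 × 24 = 1.277 → 1.3); only the
internally consistent printed values are asserted.

Mapping a score shift onto a choline-requirement shift requires a monotone
dose–response curve (dose mg/kg → expected score) supplied by the user as a
CSV table; the curve behind the published ≈ 650 / 450 / 250 / 100 mg/kg
indications is external to this package and is deliberately not bundled, so
those numbers are validated only in the sense that the inversion machinery
matches brute-force grid inversion on synthetic curves to within one node
spacing.  Inversion interpolates linearly between nodes, returns the lowest
dose on a plateau, and refuses to extrapolate.  Every output is flagged
`is_indication=True` and the report layer repeats the caveat: these are
indications of magnitude under borrowed dose–response conditions, not
requirement estimates.

## Synthetic generators

All generators are pure functions of (configuration, seed) using
numpy's `default_rng`; no global state.  Defaults are the trial conditions:
the 2 × 6 design, twelve scored fish per pen, 0.1 % dietary yttrium oxide.
`gen_pen_responses` draws one Gaussian response per cell under any of
m1–m5 (`sigma=0` gives exact means, making estimator round-trips exact by
construction).  `gen_histology_scores` draws multinomial counts from
proportional-odds probabilities.  `gen_digestibility_trial` fixes the
faeces marker at `marker_feed × concentration_factor` and solves the faeces
nutrient fraction from the AD formula, so noise-free recovery is the exact
identity; optional multiplicative lognormal noise `exp(sd · z)` leaves the
recovered AD unbiased to first order (bias (100 − AD)(e^{sd²/2} − 1), about
2.5e-4 %-units at sd = 0.01).  `gen_dose_response` tabulates linear or
decreasing-logistic curves and validates monotonicity.

What the generators do not emulate: pen-to-pen heteroscedasticity, non-
Gaussian measurement error, within-pen fish correlation, seasonal drift in
covariates, or compositional closure of fatty-acid profiles.  Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to real-data violations of them.

## Test-suite problem sizes

Simulation-based tests use sizes chosen to keep the default run fast while
leaving comfortable margins: model-recovery 120 seeds (≥ 95 % recovery
asserted with near-certain effects, standardized ≥ 5), no-effect Occam
comparison 60 seeds, KS null calibration 500 simulations at n = 12, ordinal
recovery 60 seeds at 60 fish per cell, Wald type-I 300 seeds, Monte-Carlo
bracketing of the tau quadrature 1e6 prior draws through a vectorised
closed form.  Tolerances follow the corresponding oracle error: 1e-5 log
units against grid quadrature, 1e-6 for quadrature self-convergence, one
grid step for curve inversion.
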