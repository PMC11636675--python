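# Methods

## The simulation design

The toolkit evaluates how accurately a normative-modelling method recovers
outer percentile curves (defaults: 1st, 5th, 10th) of an age-conditioned
biomarker distribution, as a function of training sample size. Everything
rests on an *analytic* ground truth g(y|x): a Gaussian conditional
distribution whose mean μ(x) and standard deviation σ(x) are smooth
functions of age x over [45, 80] years. Because μ, σ, G and the true
percentile curves y_g(x, p) are available in closed form, the bias of an
estimator is directly measurable — the quantity that is essentially
inaccessible with real data.

Two built-in ground truths cover the simplest and a plausible harder case:

| name | μ(x) | σ(x) |
|---|---|---|
| `LinMean_ConstVar` | 5000 − 7x | 300 |
| `NonLinMean_NonConstVar` | −70(x−65)·s((x−65)/10) + 20(x−65) + 6000 | 5(x−65)·s((x−65)/10) + (x−65) + 200 |

with s the logistic sigmoid. The nonlinear mean blends two asymptotic
lines (slope +20 below, −50 above) with a peak near age 63 and anchor
values μ(65) = 6000 mm³, σ(65) = 200 mm³ — biologically plausible for
total hippocampal volume in a late-middle-age cohort. Non-Gaussian
conditional families can be registered programmatically; the built-ins are
Gaussian deliberately, so that failures of the fitted models cannot be
blamed on an exotic truth.

**Age design.** Ages are drawn once per sample size from a piecewise-linear
density and then *fixed across all replicates of that size*; only the
biomarker values are redrawn. This isolates the sampling noise in the
values as the single varying factor. The default density (relative heights
0.2/0.8/1.0/0.9/0.1 at ages 45/55/62/70/80) emulates a large imaging
cohort's characteristic thinning toward both ends of the age range; it is
fully configurable, and draws use the exact piecewise-quadratic inverse
cdf. The published histogram this emulates is not available numerically,
so the breakpoint heights are a qualitative match, not a reproduction.

**Seeding.** Every random stream derives from
`SeedSequence([base_seed, n, replicate_index])`, so any replicate
regenerates bitwise-identically, in any order, across processes — the
parallelism contract is simply "replicates are independent".

## Response families

Both fitted families are four-parameter transformations of a standard
reference variable:

* **SHASH** (sinh-arcsinh, original Jones–Pewsey form):
  z = sinh(τ·asinh((y−μ)/σ) − ν) is standard normal. Chosen over the other
  common variants because it reduces *exactly* to N(μ, σ²) at ν = 0, τ = 1
  and is affinely equivariant — both properties are load-bearing in the
  tests. Quantile: y = μ + σ·sinh((asinh(Φ⁻¹(p)) + ν)/τ).
* **BCT** (Box-Cox t, Rigby–Stasinopoulos parameterisation):
  z = ((y/μ)^ν − 1)/(νσ) (log form at ν = 0) follows a t distribution with
  τ degrees of freedom, truncated to respect y > 0 and renormalised by the
  t mass at 1/(σ|ν|). For realistic fitted parameters the truncation mass
  correction is ≈ 1 and numerically harmless.

Log-densities are computed from closed forms (log-cosh identities for
SHASH), never by differencing cdfs; they stay finite 20+ scale units into
the tails.

## Fitting methods

### Sliding windows

Model-free baselines. At each grid age (0.25-year steps over the range)
take the empirical quantile — linear interpolation of order statistics,
the "type 7" rule — of the values in either a fixed ±2.5-year window
(`SliWinW5`) or of the ⌈0.10·Ns⌉ participants nearest in age
(`SliWinP10`; ties broken by participant index). The raw curves are then
smoothed along the grid with a Gaussian kernel of FWHM 5 years, kernel
weights renormalised where truncated at the grid edges (so a constant
curve passes through unchanged; no data are invented beyond the observed
range). Fixed windows holding fewer than max(5, ⌈1/min(p, 1−p)⌉/4) points
are returned flagged invalid rather than dropped. If smoothing makes
curves cross, values are sorted within each grid age (rearrangement) and
the event recorded in the fit metadata.

### Distributional regression

A GAMLSS-style penalized maximum-likelihood fitter. Each distribution
parameter has a linear predictor through its link (identity for location
and skew/power; log for scale and tail/dof). Structures: `linear`
(location linear in age, everything else constant), `mu_spline`, and
`mu_sigma_spline` (location and log-scale penalized cubic splines).
Skewness and tail parameters are always age-constant — flexible location
and scale with constant shape is the regime of practical interest here,
and it keeps the outer-percentile comparison between families fair.

**Spline smoother.** P-splines: a cubic B-spline basis on uniform knots
(7 interior segments, knots extended beyond each boundary) with a
second-difference coefficient penalty whose null space is exactly
{constant, linear}. The smoothing weight λ is calibrated by bisection on
log λ so that the effective degrees of freedom *beyond the line* — trace
of the least-squares hat matrix minus 2 — equals the target (default 3,
the familiar `cs(df=3)` convention counting df in addition to the linear
part; the target is configurable to cover the other accounting). Because
the edf of a penalized *likelihood* smoother depends on the per-observation
Fisher information of its linear predictor, the least-squares-calibrated λ
is rescaled before entering the likelihood: by 1/σ̂² for the identity-link
location (σ̂ = residual sd of the initial fit) and by 2 for the log-link
scale (the Gaussian information of log σ). Omitting this rescaling
inflates the location penalty by the residual variance (~4×10⁴ here) and
silently collapses the spline to a straight line.

**Optimisation.** Cyclic block ascent: each parameter's coefficient block
is refit by L-BFGS-B holding the others fixed (analytic score for SHASH,
finite differences for BCT), cycling until the relative change in
penalized log-likelihood falls below 1e−6 (max 200 cycles). A block
proposal that would lower the objective is rejected, so the recorded trace
is non-decreasing; this is a monotone ascent to a stationary point, not
the exact Rigby–Stasinopoulos IRLS, which is all the bias/variance
comparisons require. Non-finite likelihoods during a line search behave as
+∞ and trigger backtracking. Initialisation: location by penalized least
squares; log-scale from the global (or rolling, for `mu_sigma_spline`)
residual sd; ν = 0, τ = 1 (SHASH) or ν = 1, τ = 10 (BCT). On
non-convergence the fit restarts once from jittered initial values and
otherwise returns `converged=False` with diagnostics instead of raising.
Constant-response degeneracies are guarded by a 1e−8 floor on the scale.

**Prediction** evaluates each parameter's predictor at the grid ages
through its inverse link and applies the family quantile function, which
guarantees monotonicity across percentiles. No extrapolation: predicting
outside the fit's age range is an error. The experiment runner passes the
ground truth's full age range as the basis/prediction span so that curves
are defined at the exact range ends even when no participant sits there.

## Error measures and summaries

E1 (biomarker units) and E2 (probability units) are computed on an
integer-age evaluation grid 45–80 (36 points; results are insensitive to
the grid for curves this smooth). Percentile spacing makes the two scales
diverge in the tail: locally E1/E2 ≈ σ(x)/φ(Φ⁻¹(p)), so at p = 0.01 a
0.5-percentage-point E2 corresponds to over 27 mm³ of E1 where σ = 200,
versus about 9 mm³ at p = 0.05.

Cross-replicate summaries per age: 95% range (P97.5 − P2.5) of E1
(variance only), mean |E2| (bias + variance; E2 has a floor at −p),
median E1 (bias), IQR of E1 (variance). E1 metrics are also expressed as
percent of the mean volume, the mean of μ(x) over the integer-age grid
(configurable). Age-averaged values weight each grid age equally —
deliberately not participant-weighted, so edge behaviour is not diluted by
the well-sampled middle. Summary quantiles use the same type-7 definition
as the window fitter. Invalid grid points propagate as missing values and
are counted, never silently dropped.

The binomial helper ⌈p(1−p)/h²⌉ (smallest N with √(p(1−p)/N) ≤ h) gives
the model-free single-bin lower bound that the power reports attach as
context.

## Experiment scale

The desk-scale default is Ns ∈ {100, 500, 2000}, Nd = 50 replicates, both
ground truths, methods {SliWinW5, SliWinP10, SHASH-linear, SHASH-μ-σ};
the `paper` preset extends to Ns up to 50,000, Nd = 100, and all eight
methods. The acceptance tests run Ns ∈ {500, 2000, 5000} with Nd = 50 on
the nonlinear truth — chosen as the smallest grid on which the three
qualitative findings (monotone error-range decrease with Ns, the linear
model's bias floor, edge-age uncertainty inflation) are stable and
cleanly separated from replicate noise, while a full suite run stays
inside a coffee break. Headline-scale runs (Nd = 1000) are a configuration
choice, not a code change.

## What passing tests do and do not show

The generator draws Gaussian values around smooth parameter curves on a
fixed age design. Passing tests therefore demonstrate correct recovery
behaviour *under these conditions*: they do not speak to site/scanner
effects, measurement harmonisation, non-Gaussian conditional shapes,
age-varying skewness, covariates beyond age, or age designs that vary
between cohorts. Real-data percentile accuracy will generally be worse
than the simulation's, since age variability and model misspecification
add error sources the protocol deliberately holds fixed.

## Known limitations

* Only age as a covariate; one scalar response.
* The block-ascent optimiser finds a stationary point, not a certified
  global optimum; the nested-structure likelihood ordering is verified
  statistically, within a small tolerance.
* BCT block updates use finite-difference gradients and are several times
  slower than SHASH; BCT fits also require strictly positive responses
  (the simulator rejects offending replicates for BCT only — vanishingly
  rare at these parameter values — and logs the rejection).
* No extrapolation beyond the modelled age range, by design; behaviour at
  the exact range ends is already the least reliable part of any fit, and
  the per-age summaries are the tool for quantifying that.
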