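# Methods

## Estimand and data model

The package estimates S_GMI(δ) = P(TTP₂/TTP₁ > δ) from paired failure times
in which the first time is always observed (patients enter the trial at
their first progression) and only the second may be right-censored. The
ratio GMI = TTP₂/TTP₁ is itself a nonnegative, possibly right-censored
random variable and is treated as a time-to-event variable on the ratio
scale: S_GMI(δ) is its survival function at δ. Times are stored as unitless
positive reals; months are a documentation convention only, since every
estimator is invariant under a common rescaling of time (a tested property).
Exact ties TTP₂ = δ·TTP₁ are legal inputs; each estimator documents its own
tie convention below.

## Nonparametric midrank estimator

Each observation is an interval: [t, t] when exact, [t, ∞) when censored.
The n thresholded first-line times δ·TTP₁ᵢ (always exact) are pooled with
the n second-line intervals, and each interval j in the pooled set of 2n
receives

- min_rank(j) = 1 + #{k : R_k < L_j} — one plus the number of intervals that
  surely end before j begins;
- max_rank(j) = #{k : L_k ≤ R_j} — the number that begin no later than j
  ends (j itself included);
- midrank M_j = (min_rank + max_rank)/2.

The estimate is (1/n)·#{i : M₂ᵢ ≥ M′₁ᵢ}.

*Tie conventions.* min_rank counts strictly smaller right bounds; max_rank
counts left bounds ≤ the item's right bound. With exact, distinct data this
reduces to ordinary ranks 1..2n, and with exact ties to classical midranks.
The "≥" in the indicator is literal: a patient whose two midranks coincide
exactly counts as a responder. For a censored interval the right bound is
+∞, so max_rank = 2n always; censoring an observation at its own value can
therefore only increase its midrank and never decreases the estimate
(tested). With no censoring the estimator equals the direct proportion
#{TTP₂ ≥ δ·TTP₁}/n exactly (a randomised acceptance property).

*Confidence interval.* Wald binomial on the probability scale:
se = √(p̂(1−p̂)/n), p̂ ± z·se truncated to [0, 1], no continuity correction.
This form reproduces, from the printed estimate/sample-size pairs alone, the
published nonparametric intervals that pin the convention down (0.24 with
n = 129 → [0.17; 0.31]; 0.27 with n = 92 → [0.18; 0.36]). It is treated as
a convention choice, not a claim of optimality; it is anticonservative for
p̂ near 0 or 1 at small n.

## Parametric log-logistic estimator

If, conditionally on a shared frailty u, the two times are Weibull with a
common shape a and scales b₁u, b₂u, the ratio is marginally log-logistic —

f(δ; a, κ) = aκᵃδ^{a−1}(1 + (δκ)ᵃ)⁻²,  S(δ; a, κ) = (1 + (δκ)ᵃ)⁻¹,
κ = b₁/b₂ —

independent of the frailty. The estimator maximises the censored-ratio
likelihood Σ_events log f(rᵢ) + Σ_censored log S(rᵢ) over (log a, log κ)
(positivity without box constraints) and plugs (â, κ̂) into S.

*Numerics.* Damped Newton–Raphson with analytic gradient and Hessian, BFGS
fallback; starting values from the logistic log-ratio moments (location
−log κ, scale 1/a, estimated from the uncensored ratios); convergence at
gradient norm < 1e−8 within 500 iterations, failures raised with
diagnostics, never silently accepted. At least two exact ratios are
required: with fewer the likelihood is unbounded and the fit refuses. The
covariance is the inverse observed information at the optimum; the SE of
S(δ) follows by the delta method through (log a, log κ), and the interval is
symmetric Wald on the probability scale (the probability — not logit —
scale is chosen because it is the form consistent with published symmetric
parametric intervals for this estimand; see the CI-convention tests).

*A deliberate model violation.* The likelihood treats censoring of the ratio
as independent of the ratio. Under the actual mechanism — uniform censoring
of TTP₂ — the ratio is censored at C/TTP₁, which is correlated with the
ratio through TTP₁. This misspecification is a real feature of the method
being studied and a known source of its upward bias under censoring; the
simulation experiment exists to quantify it, so it must not be "corrected"
away.

*Diagnostic.* `km_gmi` overlays the product-limit (Kaplan–Meier, via
lifelines) survival of the ratio sample on the fitted parametric curve; on
large correctly specified samples the two agree within KM confidence-band
width (tested at n = 4000).

## Shared-frailty dependence model

Patient-level dependence between the two times is modelled by a shared
multiplicative frailty on both Weibull hazards. For a gamma frailty with
mean 1 and variance θ, Kendall's τ = θ/(θ+2), inverted as θ = 2τ/(1−τ).
Since each cluster has at most two events, the frailty integrates out in
closed form (Laplace-transform derivatives): with D = 1 + event₂,
H = (t₁/b₁)ᵃ + (t₂/b₂)ᵃ,

loglik contribution = Σ_j d_j log h_j(t_j) + Σ_{k<D} log(1+kθ)
                      − (1/θ + D) log(1 + θH),

which degenerates continuously to the independent Weibull log-likelihood as
θ → 0 (computed with `log1p`; verified against per-patient numeric
quadrature to 1e−6 relative tolerance — the module's central correctness
check). The inverse Gaussian family uses
L(s) = exp((1/θ)(1 − √(1+2θs))) and its first two derivatives, with the
cancellation-free rewrite (1−√(1+2θs))/θ = −2s/(1+√(1+2θs)); it exists for
AIC-based family comparison. AIC = −2·loglik + 2·(number of nominal free
parameters: 4 with a common shape, 5 with line-specific shapes).

*Fitting.* Direct maximisation (Nelder–Mead polish + BFGS) over
(log a, log b₁, log b₂, log θ), with a separate explicit θ = 0 fit; if the
independence fit attains the larger likelihood the boundary estimate θ̂ = 0
is reported with `boundary_theta=True` — a meaningful scientific outcome,
not an error. The common-shape fit is the default because the parametric
GMI estimator requires it; line-specific shapes are available as a
diagnostic, and both options are surfaced because published frailty
applications do not always state which was used.

## Simulator

A scenario is (τ, a, e, censoring rate r, n patients, b₁). Generation:
uᵢ ~ Gamma(1/θ, θ) (θ = 0 → uᵢ ≡ 1), then each time t = b_j·(E/uᵢ)^{1/a}
with E unit exponential, b₂ = b₁·e. By construction e is the median GMI and
the uncensored ratio sample is exactly log-logistic(a, κ = 1/e), giving the
closed-form truth S_GMI(δ) = (1+(δ/e)ᵃ)⁻¹ against which bias is defined
(both facts are tested distributionally at n = 10⁵).

Censoring: C ~ Uniform(0, c) applied to TTP₂ only; event₂ = 1 iff TTP₂ < C
strictly (an exact tie, a measure-zero event, counts as censored). The bound
c solves (1/c)∫₀ᶜ S₂(t) dt = r by Brent's method (relative tolerance 1e−8
on the root, adaptive quadrature for the integral), where
S₂(t) = (1+θ(t/b₂)ᵃ)^{−1/θ} is the *marginal* (frailty-integrated) survival
of TTP₂ — so the realised censoring fraction matches r in expectation across
patients, not within each frailty stratum. In the exponential independent
case (a = 1, θ = 0) the censoring probability has the closed form
(b₂/c)(1−e^{−c/b₂}), used as an analytic oracle in the tests.

Defaults: **n = 50 patients per trial** — a typical single-arm phase II
size, chosen once as this package's study condition since the quantity is
not fixed by the experiment being emulated (the grid-level bias summaries
turn out to be insensitive enough for the published summaries to be matched
within Monte-Carlo tolerance at this n). b₁ is anchored so the median TTP₁
is ≈16 months at a = 0.5, 9 at a = 1, 6 at a = 2 (nearest anchor for other
shapes) — cosmetic, since the GMI law depends on (a, e) only; the tested
scale-invariance property makes this explicit. All randomness flows through
one seeded `numpy` generator; any scenario is bit-reproducible from
(scenario, seed).

*What the generator does not emulate:* interval-censored assessment
schedules (progression is only ever seen at visits in real trials),
informative or non-uniform censoring, covariates, accrual patterns, and
left-censoring of TTP₁ by toxicity-driven treatment interruption. Passing
tests therefore certify the estimators under the stated generating
mechanism, not under these real-data complications.

## Simulation experiment

The full grid is τ ∈ {0.1, 0.2, 0.3} × a ∈ {0.5, 1, 2} × e ∈ {0.77, 1,
1.33} × r ∈ {10 %, 40 %} — 54 cells. Per cell and per estimator (at δ = 1
by default; δ ∈ {0.77, 1, 1.33} accepted): mean bias against the
closed-form truth, ASE (mean of estimated SEs), ESE (SD of estimates;
ASE < ESE flags anticonservative intervals). Replicates where the
parametric fit fails are excluded from that method's summary and counted —
never retried, which would hide a selection effect. Per-scenario seeds are
spawned from the master seed so cells are independently reproducible.

**Replication is 1,000 per cell by default** (the package's desk-scale
study condition; the experiment it emulates used 10,000), so summary
comparisons carry a Monte-Carlo tolerance of three per-scenario SEs
(ese/√reps ≈ 0.002) plus 0.01 for the per-trial sample size the original
experiment did not report. At this scale the full grid runs in about a
minute on one CPU.

## Known limitations

- The Wald binomial interval is poor near boundary proportions; no exact or
  score interval is offered.
- The parametric estimator's bias under censoring is structural (see above);
  it is reported, not corrected.
- Frailty fits use numeric optimisation without analytic derivatives; no
  standard error for τ̂ is reported (replicate-based SEs are used in the
  tests instead).
- Covariates, multi-centre stratification, more than two treatment lines,
  positive stable frailty, and interval- or left-censored ratios are out of
  scope.
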