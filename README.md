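# gmisurv

Estimation of the **growth modulation index (GMI)** exceedance probability in
single-arm phase II oncology trials.

In trials of a new agent given after a failed treatment line, each patient
serves as their own historical control: with TTP₁ the time to progression on
the previous line (always observed, since patients enter at their first
progression) and TTP₂ the time to progression on the new line (possibly
right-censored at analysis), the GMI is the ratio TTP₂/TTP₁ and the trial's
estimand is

S_GMI(δ) = P(TTP₂/TTP₁ > δ),  δ ≥ 0,

typically reported at δ = 0.77 (second-line inactivity), 1 (equivalence) or
1.33 (activity). Because TTP₂ — and hence the ratio — may be right-censored,
a naive responder proportion is biased; `gmisurv` implements two estimators
that handle censoring:

- **Nonparametric (midrank).** Each time becomes an interval ([t, t] if
  exact, [t, ∞) if censored). The n thresholded first-line times δ·TTP₁ are
  pooled with the n second-line times and each interval gets a *midrank* —
  the midpoint of the smallest and largest rank it could take in the pooled
  sample of 2n. The estimate is (1/n)·#{i : M₂ᵢ ≥ M′₁ᵢ}, with a Wald binomial
  confidence interval.
- **Parametric (log-logistic).** If, conditionally on a shared patient
  frailty, both times are Weibull with common shape a and scales b₁, b₂, the
  ratio is marginally log-logistic with survival S(δ) = (1 + (δκ)ᵃ)⁻¹,
  κ = b₁/b₂, free of the frailty. The censored-ratio maximum-likelihood fit
  of (a, κ) gives a plug-in estimate with a delta-method Wald interval, and a
  Kaplan–Meier overlay (`diagnose`) checks the distributional assumption.

The package also fits shared **gamma-frailty** (and inverse Gaussian) Weibull
models to quantify the intra-patient dependence via Kendall's
τ = θ/(θ + 2), simulates trials with exactly this structure (gamma frailty,
conditional Weibull margins, scale ratio e = median GMI, uniform censoring
calibrated to a target rate), and reruns the full 54-scenario operating-
characteristics experiment (bias, average and empirical standard errors of
both estimators).

## Worked example

Simulate a phase-II-like trial (n = 129, ≈12 % of second times censored,
τ ≈ 0.2) and estimate S_GMI(δ):

```sh
gmisurv fixture --kind phase2_like --seed 11 -o demo.csv
gmisurv estimate --delta 1 --delta 1.33 demo.csv
```

```
method           delta  estimate      se  ci_low  ci_high  level     n  events
------------------------------------------------------------------------------
nonparametric        1    0.5271  0.0440  0.4410   0.6133   0.95   129     111
parametric           1    0.5121  0.0391  0.4355   0.5888   0.95   129     111
nonparametric     1.33    0.4651  0.0439  0.3790   0.5512   0.95   129     111
parametric        1.33    0.4538  0.0391  0.3772   0.5305   0.95   129     111
```

About 53 % of patients progress later on the second line than on the first
(GMI > 1), with a 95 % CI of roughly [0.44, 0.61] — both estimators agree
closely here because censoring is light. `gmisurv tau demo.csv` fits the
gamma-frailty Weibull model to the same file and reports θ̂ = 0.43,
τ̂ = 0.18 (AIC 1877.6): a modest intra-patient correlation, close to the
τ = 0.2 the fixture was generated with.

Other subcommands: `simulate` (write synthetic trials for any scenario),
`study` (run a scenario grid and summarise bias/ASE/ESE), `diagnose`
(Kaplan–Meier vs fitted log-logistic survival of the GMI as a two-curve
table). Library use mirrors the CLI:

```python
from gmisurv import read_trial, estimate_nonparametric, estimate_parametric
data = read_trial("demo.csv")
est = estimate_nonparametric(data, delta=1.0)   # EstimateWithCI
```

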