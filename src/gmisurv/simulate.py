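"""Trial simulator: gamma frailty, conditional Weibull times, uniform censoring.

One simulated trial draws, per patient, a frailty u ~ Gamma(mean 1,
variance theta) with theta = 2*tau/(1 - tau), then two conditionally
independent Weibull times with common shape a and scales b1 and b2 = b1 * e
(survival exp(-u * (t/b_j)^a), sampled as t = b_j * (E/u)^(1/a) with E unit
exponential). The effect size e is by construction the median of the GMI
TTP2/TTP1, whose marginal law is log-logistic(a, kappa = 1/e) regardless of
the frailty or of b1 — so the estimand S_GMI(delta) = (1 + (delta/e)^a)^(-1)
depends on (a, e) only, and b1 is a cosmetic time scale.

Right censoring applies to TTP2 only (TTP1 is observed by design): each
patient gets an independent C ~ Uniform(0, c) and records min(TTP2, C). The
support bound c is calibrated so the marginal (frailty-integrated) censoring
probability (1/c) * integral_0^c S2(t) dt equals the target rate, where
S2(t) = (1 + theta * (t/b2)^a)^(-1/theta) is the marginal survival of TTP2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import integrate, optimize

from .data_model import PairedTrialData
from .frailty import theta_from_tau

__all__ = [
    "Scenario",
    "TrueValues",
    "default_scale_b1",
    "true_values",
    "draw_frailties",
    "draw_paired_times",
    "calibrate_censoring_bound",
    "apply_censoring",
    "simulate_trial",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_scale_b1(shape_a: float) -> float:
    """First-line Weibull scale anchored to typical median TTP1 values.

    Roughly 16 months for slowly progressing disease (a = 0.5), 9 months at
    a = 1, and 6 months for aggressive disease (a = 2); the nearest anchor is
    used for other shapes. Cosmetic only: the GMI distribution — hence both
    estimators — is invariant to this time scale.
    """
    if shape_a <= 0:
        raise ValueError("shape must be positive")
    median = 16.0 if shape_a <= 0.75 else (6.0 if shape_a >= 1.5 else 9.0)
    return median / np.log(2.0) ** (1.0 / shape_a)


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: dependence, shape, effect, censoring, size."""

    tau: float
    shape_a: float
    effect_e: float
    censor_rate: float
    n_patients: int = 50
    scale_b1: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must be in [0, 1)")
        if self.shape_a <= 0 or self.effect_e <= 0:
            raise ValueError("shape_a and effect_e must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.scale_b1 is None:
            object.__setattr__(self, "scale_b1", default_scale_b1(self.shape_a))
        elif self.scale_b1 <= 0:
            raise ValueError("scale_b1 must be positive")

    @property
    def theta(self) -> float:
        return theta_from_tau(self.tau)

    @property
    def scale_b2(self) -> float:
        return self.scale_b1 * self.effect_e


@dataclass(frozen=True)
class TrueValues:
    """Closed-form truth of a scenario: the log-logistic GMI law."""

    shape_a: float
    effect_e: float

    def s_gmi_at(self, delta: float) -> float:
        """True S_GMI(delta) = (1 + (delta/e)^a)^(-1); equals 1/2 at delta=e."""
        return 1.0 / (1.0 + (delta / self.effect_e) ** self.shape_a)

    @property
    def median_gmi(self) -> float:
        return self.effect_e


def true_values(scenario: Scenario) -> TrueValues:
    return TrueValues(scenario.shape_a, scenario.effect_e)


def draw_frailties(theta: float, n: int, seed=None) -> np.ndarray:
    """n i.i.d. gamma frailties with mean 1 and variance theta (theta=0 -> ones)."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta == 0.0:
        return np.ones(n)
    rng = _as_rng(seed)
    return rng.gamma(shape=1.0 / theta, scale=theta, size=n)


def draw_paired_times(scenario: Scenario, seed=None) -> PairedTrialData:
    """One trial's paired times, pre-censoring (both event indicators 1)."""
    rng = _as_rng(seed)
    n = scenario.n_patients
    u = draw_frailties(scenario.theta, n, rng)
    e1 = rng.exponential(size=n)
    e2 = rng.exponential(size=n)
    a = scenario.shape_a
    ttp1 = scenario.scale_b1 * (e1 / u) ** (1.0 / a)
    ttp2 = scenario.scale_b2 * (e2 / u) ** (1.0 / a)
    return PairedTrialData(ttp1, ttp2, np.ones(n, dtype=int))


def marginal_survival_ttp2(scenario: Scenario) -> Callable[[np.ndarray], np.ndarray]:
    """Frailty-integrated survival of TTP2: (1+theta*(t/b2)^a)^(-1/theta)."""
    theta, a, b2 = scenario.theta, scenario.shape_a, scenario.scale_b2
    if theta == 0.0:
        return lambda t: np.exp(-((np.asarray(t) / b2) ** a))
    return lambda t: (1.0 + theta * (np.asarray(t) / b2) ** a) ** (-1.0 / theta)


def calibrate_censoring_bound(
    scenario: Scenario, target_rate: float | None = None
) -> float:
    """Upper bound c of the Uniform(0, c) censoring law hitting a target rate.

    Solves (1/c) * integral_0^c S2(t) dt = r numerically (relative tolerance
    1e-6), where S2 is the marginal survival of TTP2. The left side decreases
    monotonically from 1 (c -> 0) to 0 (c -> infinity), so a root exists for
    any r in (0, 1).
    """
    r = scenario.censor_rate if target_rate is None else target_rate
    if not 0.0 < r < 1.0:
        raise ValueError("target censoring rate must be in (0, 1)")
    s2 = marginal_survival_ttp2(scenario)

    def censor_prob(c: float) -> float:
        val, _ = integrate.quad(s2, 0.0, c, limit=200)
        return val / c

    b2 = scenario.scale_b2
    lo, hi = 1e-6 * b2, b2
    for _ in range(200):
        if censor_prob(hi) < r:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"no censoring bound found below {hi:.3g} for target rate {r}"
        )
    c = optimize.brentq(lambda c: censor_prob(c) - r, lo, hi, rtol=1e-8)
    return float(c)


def apply_censoring(data: PairedTrialData, bound: float, seed=None) -> PairedTrialData:
    """Censor ttp2 by an independent Uniform(0, bound) variable per patient.

    Records min(ttp2, C) and event2 = 1 iff ttp2 < C strictly (an exact tie —
    a measure-zero event — is recorded as censored). ttp1 is untouched.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    rng = _as_rng(seed)
    c = rng.uniform(0.0, bound, size=data.n)
    observed = data.ttp2 < c
    return PairedTrialData(
        data.ttp1,
        np.minimum(data.ttp2, c),
        (observed & (data.event2 == 1)).astype(int),
    )


def simulate_trial(
    scenario: Scenario, seed=None, censor_bound: float | None = None
) -> PairedTrialData:
    """Draw one complete trial: paired times plus calibrated uniform censoring.

    ``censor_bound`` short-circuits the calibration (useful when simulating
    many replicates of the same scenario).
    """
    rng = _as_rng(seed)
    data = draw_paired_times(scenario, rng)
    if scenario.censor_rate > 0.0:
        if censor_bound is None:
            censor_bound = calibrate_censoring_bound(scenario)
        data = apply_censoring(data, censor_bound, rng)
    return data
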