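"""Probability-of-success measures for a planned one-sided trial.

Four pre-experimental summaries of a level-α one-sided z-test under a
design prior π on the effect θ (p0 = P(Θ ≤ θ0), p1 = 1 − p0):

* ``u``   — u-PoS, the Bayes 0–1 utility of the test: the prior-expected
  probability of choosing the TRUE hypothesis, u = p0·u0 + p1·u1 where
  u0 = E[1 − η_n(Θ) | Ω0] and u1 = E[η_n(Θ) | Ω1];
* ``e_a`` — joint probability of rejecting H0 and Θ ∈ Ω1: e_a = p1·u1;
* ``e_b`` — conditional expected power E[η_n(Θ) | Θ ∈ Ω1] = u1;
* ``e_c`` — assurance, the marginal rejection probability E[η_n(Θ)]
  = p0·(1 − u0) + p1·u1.

As n → ∞ (size-α consistency of the z-test) u and e_b tend to 1 for any
proper design prior, while e_a and e_c tend to p1 < 1 whenever the prior
leaves mass on the null — the reason threshold-based sample-size rules for
e_a/e_c need a feasibility check (see :mod:`upos.ssd`).

Estimation routes: seeded Monte Carlo over common prior draws
(:func:`mc_estimate`), deterministic adaptive quadrature
(:func:`quad_estimate`), and, for assurance under a conventional normal
prior, the closed form :func:`enc_closed_form`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .design_priors import DesignPrior, NormalPrior, VariancePrior, sample_joint
from .test_model import OneSidedTest

__all__ = [
    "PoSResult",
    "LimitSet",
    "mc_estimate",
    "quad_estimate",
    "enc_closed_form",
    "limits",
    "measures_with_variance_prior",
]


@dataclass(frozen=True)
class PoSResult:
    """The four PoS measures at one sample size, with their decomposition.

    ``u0``/``u1`` are the conditional Bayes utilities under the null and
    the alternative; either is NaN when its region has zero prior mass.
    MC results carry the number of draws ``M``, the ``seed`` and one
    standard error per measure; quadrature and closed-form results are
    deterministic and leave those fields at None.
    """

    n: int
    u: float
    e_a: float
    e_b: float
    e_c: float
    u0: float
    u1: float
    p0: float
    p1: float
    method: str
    M: int | None = None
    seed: int | None = None
    se_u: float | None = None
    se_a: float | None = None
    se_b: float | None = None
    se_c: float | None = None

    def measure(self, name: str) -> float:
        """Value of one measure by short name 'u' | 'a' | 'b' | 'c'."""
        return {"u": self.u, "a": self.e_a, "b": self.e_b, "c": self.e_c}[name]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LimitSet:
    """n → ∞ limits of the four measures under a size-α consistent test."""

    u_inf: float
    e_a_inf: float
    e_b_inf: float
    e_c_inf: float

    def limit(self, name: str) -> float:
        return {"u": self.u_inf, "a": self.e_a_inf, "b": self.e_b_inf, "c": self.e_c_inf}[name]


def _mc_from_draws(test, n, eta, in_alt, p0, p1, M, seed) -> PoSResult:
    """Assemble the four estimators from one common set of power draws."""
    in_null = ~in_alt
    p1_bar = in_alt.mean()
    u_terms = np.where(in_alt, eta, 1.0 - eta)
    a_terms = eta * in_alt
    root_M = math.sqrt(M)

    if in_alt.any():
        e_b = float(a_terms.sum() / in_alt.sum())
        # delta-method SE of the ratio estimator e_a / p̄1
        se_b = float(np.sqrt(np.mean((in_alt * (eta - e_b)) ** 2)) / (p1_bar * root_M))
    else:
        if p1 > 0:
            warnings.warn(
                "no draws fell in the alternative region: e_b is undefined "
                "for this sample (increase M)",
                RuntimeWarning,
            )
        e_b = math.nan
        se_b = math.nan

    u1 = e_b
    u0 = float((1.0 - eta)[in_null].mean()) if in_null.any() else math.nan

    return PoSResult(
        n=int(n),
        u=float(u_terms.mean()),
        e_a=float(a_terms.mean()),
        e_b=e_b,
        e_c=float(eta.mean()),
        u0=u0,
        u1=u1,
        p0=p0,
        p1=p1,
        method="mc",
        M=int(M),
        seed=seed,
        se_u=float(u_terms.std(ddof=1) / root_M),
        se_a=float(a_terms.std(ddof=1) / root_M),
        se_b=se_b,
        se_c=float(eta.std(ddof=1) / root_M),
    )


def mc_estimate(
    test: OneSidedTest, prior: DesignPrior, n: int, M: int = 1_000_000, seed: int | None = None
) -> PoSResult:
    """Monte Carlo estimate of all four measures from one common draw set.

    Draws θ⁽¹⁾…θ⁽ᴹ⁾ from the design prior and averages the corresponding
    power values: e_c is the plain mean of η_n(θ⁽ʳ⁾), e_a restricts to
    draws in Ω1, e_b is the ratio estimator e_a/p̄1 with p̄1 the empirical
    alternative mass, and u averages η on Ω1 and 1 − η on Ω0. Using one
    draw set for all four keeps their comparison paired.
    """
    if M < 2:
        raise ValueError("M must be at least 2")
    theta = prior.sample(M, seed)
    eta = np.asarray(test.power(theta, n))
    in_alt = theta > test.theta0
    p0 = prior.prob_null(test.theta0)
    return _mc_from_draws(test, n, eta, in_alt, p0, 1.0 - p0, M, seed)


def quad_estimate(test: OneSidedTest, prior: DesignPrior, n: int) -> PoSResult:
    """Deterministic evaluation of the four measures by adaptive quadrature.

    Integrates η_n·π separately over Ω0 and Ω1 (the utility integrand kinks
    at θ0) with exact prior masses from the CDF; mixtures are integrated
    componentwise. For a point-mass prior this reduces to a single power
    evaluation.
    """
    theta0 = test.theta0
    p0 = prior.prob_null(theta0)
    p1 = 1.0 - p0
    eta = lambda t: test.power(t, n)  # noqa: E731
    I0 = prior.integrate(eta, -math.inf, theta0)
    I1 = prior.integrate(eta, theta0, math.inf)
    u0 = 1.0 - I0 / p0 if p0 > 0 else math.nan
    u1 = I1 / p1 if p1 > 0 else math.nan
    return PoSResult(
        n=int(n),
        u=(p0 - I0) + I1,
        e_a=I1,
        e_b=u1,
        e_c=I0 + I1,
        u0=u0,
        u1=u1,
        p0=p0,
        p1=p1,
        method="quadrature",
    )


def enc_closed_form(test: OneSidedTest, theta_d: float, n_d: float, n: int) -> float:
    """Closed-form assurance e_c under the normal prior N(θd, σ²/n_d).

    e_c = 1 − Φ((θ0 − θd + σ z_{1−α}/√n) / ξd) with ξd = σ √(1/n_d + 1/n).
    As n_d → ∞ this collapses to the frequentist power at θd.
    """
    if n_d <= 0 or n < 1:
        raise ValueError("n_d and n must be positive")
    xi_d = test.sigma * math.sqrt(1.0 / n_d + 1.0 / n)
    z = test.critical_z
    return float(
        1.0 - stats.norm.cdf((test.theta0 - theta_d + test.sigma / math.sqrt(n) * z) / xi_d)
    )


def limits(test: OneSidedTest, prior: DesignPrior) -> LimitSet:
    """n → ∞ limits: u_∞ = e_b,∞ = 1 and e_a,∞ = e_c,∞ = p1."""
    p1 = 1.0 - prior.prob_null(test.theta0)
    return LimitSet(u_inf=1.0, e_a_inf=p1, e_b_inf=1.0, e_c_inf=p1)


def measures_with_variance_prior(
    test: OneSidedTest,
    prior: NormalPrior,
    vprior: VariancePrior,
    n: int,
    M: int = 1_000_000,
    seed: int | None = None,
) -> PoSResult:
    """MC measures when σ² itself carries an inverse-gamma design prior.

    Each draw r uses σ²⁽ʳ⁾ ~ IG(a, b) both in the effect prior scale
    (θ⁽ʳ⁾ | σ²⁽ʳ⁾ ~ N(θd, σ²⁽ʳ⁾/n_d)) and in the power function evaluated
    at σ⁽ʳ⁾. Marginally θ − θd is a scaled Student-t with 2a degrees of
    freedom, which gives the exact p0 reported in the result.
    """
    if M < 2:
        raise ValueError("M must be at least 2")
    sigma2, theta = sample_joint(prior, vprior, M, seed)
    eta = np.asarray(test.power(theta, n, sigma=np.sqrt(sigma2)))
    in_alt = theta > test.theta0
    # marginal: (θ − θd)·sqrt(a·n_d/b) ~ t_{2a}
    t_scale = math.sqrt(vprior.b / (vprior.a * prior.n_d))
    p0 = float(stats.t.cdf((test.theta0 - prior.theta_d) / t_scale, df=2.0 * vprior.a))
    return _mc_from_draws(test, n, eta, in_alt, p0, 1.0 - p0, M, seed)
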