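"""One-sided z-test for a normal mean with known sampling variance.

The trial endpoint is summarised by a statistic ``X̄_n ~ Normal(θ, σ²/n)``
(in the motivating application θ is a log odds ratio and σ² = 4, so that
``n`` counts effective observations, i.e. total events across both arms).
The hypotheses are ``H0: θ ≤ θ0`` versus ``H1: θ > θ0`` and the level-α
test rejects when ``x̄_n > θ0 + σ z_{1−α}/√n``.

Besides the classical power function η_n(θ) the module exposes the
expected 0–1 utility

    U_n(θ) = 1 − η_n(θ)  on Ω0 = (−∞, θ0],
    U_n(θ) = η_n(θ)      on Ω1 = (θ0, ∞),

the probability that the test picks the true hypothesis — the frequentist
ingredient of the u-PoS measure built in :mod:`upos.pos_measures`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OneSidedTest", "normal_power", "bayes_risk_dual"]


def _check_n(n) -> None:
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError(f"sample size n must be a positive integer, got {n!r}")
    if not np.all(np.equal(np.mod(n_arr, 1), 0)):
        raise ValueError(f"sample size n must be integer-valued, got {n!r}")


def normal_power(theta, n, theta0: float, alpha: float, sigma) -> np.ndarray | float:
    """Power η_n(θ) = Φ(√n (θ − θ0)/σ − z_{1−α}) of the one-sided z-test.

    Vectorised over ``theta``, ``n`` and ``sigma`` (broadcasting applies),
    which lets callers evaluate the power under a drawn σ when the variance
    itself carries a design prior.
    """
    _check_n(n)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = stats.norm.ppf(1.0 - alpha)
    return stats.norm.cdf(np.sqrt(n) * (np.asarray(theta, dtype=float) - theta0) / sigma - z)


def bayes_risk_dual(u):
    """Bayes risk r = 1 − u dual to a Bayes utility u ∈ [0, 1]."""
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError(f"utility must lie in [0, 1], got {u!r}")
    out = 1.0 - u_arr
    return float(out) if np.isscalar(u) or out.ndim == 0 else out


@dataclass(frozen=True)
class OneSidedTest:
    """Level-α one-sided z-test of H0: θ ≤ θ0 against H1: θ > θ0.

    Parameters
    ----------
    theta0
        Boundary value of the effect (0 on the log-odds-ratio scale for a
        superiority trial).
    alpha
        One-sided significance level, in (0, 1).
    sigma
        Known per-observation sampling standard deviation (σ = 2 in the
        application, so σ² = 4).
    """

    theta0: float = 0.0
    alpha: float = 0.05
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def sigma2(self) -> float:
        return self.sigma**2

    @property
    def critical_z(self) -> float:
        """Standard-normal critical value z_{1−α}."""
        return float(stats.norm.ppf(1.0 - self.alpha))

    def power(self, theta, n, sigma=None):
        """Rejection probability η_n(θ); ``sigma`` overrides the design σ."""
        s = self.sigma if sigma is None else sigma
        return normal_power(theta, n, self.theta0, self.alpha, s)

    def type1_error(self, theta, n):
        """Type I error α_n(θ) = η_n(θ), defined only on Ω0 (θ ≤ θ0)."""
        if np.any(np.asarray(theta) > self.theta0):
            raise ValueError("type1_error is defined only for theta <= theta0")
        return self.power(theta, n)

    def type2_error(self, theta, n):
        """Type II error β_n(θ) = 1 − η_n(θ), defined only on Ω1 (θ > θ0)."""
        if np.any(np.asarray(theta) <= self.theta0):
            raise ValueError("type2_error is defined only for theta > theta0")
        return 1.0 - self.power(theta, n)

    def expected_utility(self, theta, n, sigma=None):
        """Probability U_n(θ) of choosing the true hypothesis.

        Equals 1 − η_n(θ) on Ω0 (θ0 included in the null) and η_n(θ) on Ω1.
        """
        theta_arr = np.asarray(theta, dtype=float)
        eta = self.power(theta_arr, n, sigma=sigma)
        in_null = theta_arr <= self.theta0
        out = np.where(in_null, 1.0 - eta, eta)
        return float(out) if out.ndim == 0 else out
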