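"""Design priors on the treatment effect for trial planning.

A *design prior* π(θ) expresses pre-experimental uncertainty about the true
effect and is used only at the planning stage (it is not an analysis prior:
no posterior is ever computed here). The family implemented covers the
scenarios used for a normal-endpoint superiority trial:

* :class:`PointMassPrior` — the classical conditional power setting;
* :class:`NormalPrior` — θ ~ N(θd, σ²/n_d), n_d a "prior sample size";
* :class:`SkewNormalPrior` — asymmetric uncertainty, shape λ;
* :class:`TruncatedNormalPrior` — normal restricted to [θL, θU]; with
  θL = θ0 the null region gets zero mass;
* :class:`MixturePrior` — a weighted mixture of normal components, the
  bimodal "efficacy vs. no-efficacy" consensus prior;
* :class:`VariancePrior` — an inverse-gamma law on σ² for designs where the
  sampling variance is itself uncertain.

Every prior exposes ``density``, ``cdf``, ``sample`` (seeded, reproducible),
``prob_null(theta0)`` = P(Θ ≤ θ0) evaluated exactly from the CDF, and an
``integrate`` hook used by the deterministic quadrature estimators.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as _integrate
from scipy import stats
from scipy.special import owens_t

__all__ = [
    "DesignPrior",
    "PointMassPrior",
    "NormalPrior",
    "SkewNormalPrior",
    "TruncatedNormalPrior",
    "MixturePrior",
    "ConditionalPrior",
    "VariancePrior",
    "conditional",
    "sample_joint",
    "prior_from_config",
]

#: half-width of the effective integration window, in units of the scale
_TAIL_SD = 10.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class DesignPrior(abc.ABC):
    """Abstract contract shared by all design priors."""

    @abc.abstractmethod
    def density(self, theta):
        """Prior density π(θ) (a point mass reports 0/inf conventionally)."""

    @abc.abstractmethod
    def cdf(self, theta):
        """Prior CDF P(Θ ≤ θ)."""

    @abc.abstractmethod
    def sample(self, M: int, seed=None) -> np.ndarray:
        """Draw ``M`` effects; reproducible for a given integer seed."""

    @property
    @abc.abstractmethod
    def support(self) -> tuple[float, float]:
        """Support bounds (may be infinite)."""

    def prob_null(self, theta0: float) -> float:
        """Exact prior mass p0 = P(Θ ≤ θ0) of the null region."""
        return float(self.cdf(theta0))

    def _quad_window(self) -> tuple[float, float]:
        """Finite window carrying (numerically) all the prior mass."""
        lo, hi = self.support
        return lo, hi

    def integrate(self, f, lower: float, upper: float) -> float:
        """∫ f(θ) π(θ) dθ over (lower, upper) by adaptive quadrature."""
        lo, hi = self._quad_window()
        a, b = max(lower, lo), min(upper, hi)
        if a >= b:
            return 0.0
        val, _ = _integrate.quad(lambda t: f(t) * self.density(t), a, b, limit=200)
        return float(val)


@dataclass(frozen=True)
class PointMassPrior(DesignPrior):
    """Degenerate prior at a design value θd (classical power analysis)."""

    theta_d: float

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = np.where(theta == self.theta_d, np.inf, 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = np.where(theta >= self.theta_d, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out

    def sample(self, M, seed=None):
        return np.full(int(M), self.theta_d, dtype=float)

    @property
    def support(self):
        return (self.theta_d, self.theta_d)

    def integrate(self, f, lower, upper):
        # half-open (lower, upper] convention so a mass at θ0 belongs to Ω0
        return float(f(self.theta_d)) if lower < self.theta_d <= upper else 0.0


@dataclass(frozen=True)
class NormalPrior(DesignPrior):
    """θ ~ Normal(θd, σ²/n_d); ``n_d`` is the design-prior sample size."""

    theta_d: float
    n_d: float
    sigma: float = 2.0

    def __post_init__(self):
        if self.n_d <= 0 or self.sigma <= 0:
            raise ValueError("n_d and sigma must be positive")

    @property
    def scale(self) -> float:
        return self.sigma / math.sqrt(self.n_d)

    def density(self, theta):
        return stats.norm.pdf(theta, self.theta_d, self.scale)

    def cdf(self, theta):
        return stats.norm.cdf(theta, self.theta_d, self.scale)

    def sample(self, M, seed=None):
        return _as_rng(seed).normal(self.theta_d, self.scale, int(M))

    @property
    def support(self):
        return (-np.inf, np.inf)

    def _quad_window(self):
        return (self.theta_d - _TAIL_SD * self.scale, self.theta_d + _TAIL_SD * self.scale)


@dataclass(frozen=True)
class SkewNormalPrior(DesignPrior):
    """Skew normal with location θd, scale ω = σ/√n_d and shape λ.

    The CDF is Φ(z) − 2·T(z, λ) with z = (θ − θd)/ω and T Owen's T
    function, which is how ``prob_null`` is evaluated exactly.
    """

    theta_d: float
    n_d: float
    lam: float
    sigma: float = 2.0

    def __post_init__(self):
        if self.n_d <= 0 or self.sigma <= 0:
            raise ValueError("n_d and sigma must be positive")

    @property
    def scale(self) -> float:
        return self.sigma / math.sqrt(self.n_d)

    def density(self, theta):
        z = (np.asarray(theta, dtype=float) - self.theta_d) / self.scale
        return 2.0 / self.scale * stats.norm.pdf(z) * stats.norm.cdf(self.lam * z)

    def cdf(self, theta):
        z = (np.asarray(theta, dtype=float) - self.theta_d) / self.scale
        # clip away O(1e-80) roundoff from the Φ(z) − 2T(z, λ) difference in
        # the far tails
        out = np.clip(stats.norm.cdf(z) - 2.0 * owens_t(z, self.lam), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def sample(self, M, seed=None):
        return stats.skewnorm.rvs(
            self.lam, loc=self.theta_d, scale=self.scale, size=int(M), random_state=_as_rng(seed)
        )

    @property
    def support(self):
        return (-np.inf, np.inf)

    def _quad_window(self):
        return (self.theta_d - _TAIL_SD * self.scale, self.theta_d + _TAIL_SD * self.scale)


@dataclass(frozen=True)
class TruncatedNormalPrior(DesignPrior):
    """Normal(θd, σ²/n_d) restricted to [θL, θU] (θU = inf allowed)."""

    theta_d: float
    n_d: float
    theta_L: float
    theta_U: float = np.inf
    sigma: float = 2.0

    def __post_init__(self):
        if self.n_d <= 0 or self.sigma <= 0:
            raise ValueError("n_d and sigma must be positive")
        if not self.theta_L < self.theta_U:
            raise ValueError("require theta_L < theta_U")

    @property
    def scale(self) -> float:
        return self.sigma / math.sqrt(self.n_d)

    def _frozen(self):
        a = (self.theta_L - self.theta_d) / self.scale
        b = (self.theta_U - self.theta_d) / self.scale
        return stats.truncnorm(a, b, loc=self.theta_d, scale=self.scale)

    def density(self, theta):
        return self._frozen().pdf(theta)

    def cdf(self, theta):
        return self._frozen().cdf(theta)

    def sample(self, M, seed=None):
        # scipy's truncnorm sampler is inverse-CDF based: cost is independent
        # of the truncation mass.
        return self._frozen().rvs(size=int(M), random_state=_as_rng(seed))

    @property
    def support(self):
        return (self.theta_L, self.theta_U)

    def _quad_window(self):
        lo = max(self.theta_L, self.theta_d - _TAIL_SD * self.scale)
        hi = min(self.theta_U, self.theta_d + _TAIL_SD * self.scale)
        return (lo, hi)


@dataclass(frozen=True)
class MixturePrior(DesignPrior):
    """Finite mixture of normal priors, π = Σ_h w_h π_h.

    The two-component form w0·N(θd0, σ²/n_d0) + (1−w0)·N(θd1, σ²/n_d1) is
    the bimodal consensus prior used when both a "no effect" and an
    "effective treatment" scenario carry weight at the design stage.
    """

    components: tuple[NormalPrior, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be non-empty and equal-length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def two_component(cls, prior0: NormalPrior, prior1: NormalPrior, w0: float) -> "MixturePrior":
        if not 0.0 <= w0 <= 1.0:
            raise ValueError("w0 must lie in [0, 1]")
        return cls(components=(prior0, prior1), weights=(w0, 1.0 - w0))

    def density(self, theta):
        return sum(w * c.density(theta) for w, c in zip(self.weights, self.components))

    def cdf(self, theta):
        return sum(w * c.cdf(theta) for w, c in zip(self.weights, self.components))

    def sample(self, M, seed=None):
        rng = _as_rng(seed)
        M = int(M)
        idx = rng.choice(len(self.components), size=M, p=np.asarray(self.weights))
        out = np.empty(M)
        for h, comp in enumerate(self.components):
            mask = idx == h
            out[mask] = comp.sample(int(mask.sum()), rng)
        return out

    @property
    def support(self):
        los, his = zip(*(c.support for c in self.components))
        return (min(los), max(his))

    def integrate(self, f, lower, upper):
        # componentwise: each component gets its own adaptive grid, so a
        # far-apart bimodal mixture loses no accuracy
        return sum(w * c.integrate(f, lower, upper) for w, c in zip(self.weights, self.components))


class ConditionalPrior(DesignPrior):
    """Parent prior restricted (and renormalised) to one side of θ0.

    ``side=0`` keeps Ω0 = (−∞, θ0], ``side=1`` keeps Ω1 = (θ0, ∞); the
    density is π(θ)/p_side on the kept region and 0 elsewhere.
    """

    def __init__(self, parent: DesignPrior, side: int, theta0: float):
        if side not in (0, 1):
            raise ValueError("side must be 0 or 1")
        p0 = parent.prob_null(theta0)
        p_side = p0 if side == 0 else 1.0 - p0
        if p_side <= 0.0:
            raise ValueError(
                f"conditional prior on side {side} is degenerate: the parent "
                f"prior puts mass {p_side} there"
            )
        self.parent = parent
        self.side = side
        self.theta0 = float(theta0)
        self.p_side = float(p_side)

    def _keeps(self, theta):
        theta = np.asarray(theta, dtype=float)
        return theta <= self.theta0 if self.side == 0 else theta > self.theta0

    def density(self, theta):
        out = np.where(self._keeps(theta), np.asarray(self.parent.density(theta)) / self.p_side, 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, theta):
        theta = np.asarray(theta, dtype=float)
        parent_cdf = np.asarray(self.parent.cdf(theta), dtype=float)
        if self.side == 0:
            out = np.clip(parent_cdf / self.p_side, 0.0, 1.0)
            out = np.where(theta > self.theta0, 1.0, out)
        else:
            p0 = 1.0 - self.p_side
            out = np.clip((parent_cdf - p0) / self.p_side, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def sample(self, M, seed=None):
        # rejection from the parent; expected cost M / p_side draws
        rng = _as_rng(seed)
        M = int(M)
        out = np.empty(M)
        filled = 0
        for _ in range(10_000):
            block = max(int((M - filled) / self.p_side * 1.2), 128)
            draws = self.parent.sample(block, rng)
            keep = draws[self._keeps(draws)]
            take = min(len(keep), M - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
            if filled == M:
                return out
        raise RuntimeError("rejection sampling failed to fill the request")

    @property
    def support(self):
        lo, hi = self.parent.support
        return (lo, min(hi, self.theta0)) if self.side == 0 else (max(lo, self.theta0), hi)

    def integrate(self, f, lower, upper):
        lo, hi = self.support
        return self.parent.integrate(f, max(lower, lo), min(upper, hi)) / self.p_side


def conditional(prior: DesignPrior, side: int, theta0: float) -> ConditionalPrior:
    """Restriction π̃_side of ``prior`` to Ω_side, renormalised to mass 1."""
    return ConditionalPrior(prior, side, theta0)


@dataclass(frozen=True)
class VariancePrior:
    """Inverse-gamma prior σ² ~ IG(a, b), density ∝ x^{−a−1} e^{−b/x}.

    Shape–scale parameterisation: mean b/(a−1) for a > 1. IG(16, 60) has
    mean 4 and standard deviation ≈ 1.07, the "uncertain variance" scenario
    of the application.
    """

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 1.0:
            raise ValueError("shape a must exceed 1 for the prior mean to exist")
        if self.b <= 0:
            raise ValueError("scale b must be positive")

    @property
    def mean(self) -> float:
        return self.b / (self.a - 1.0)

    @property
    def sd(self) -> float:
        if self.a <= 2.0:
            return math.inf
        return self.b / ((self.a - 1.0) * math.sqrt(self.a - 2.0))

    def density(self, x):
        return stats.invgamma.pdf(x, self.a, scale=self.b)

    def sample(self, M, seed=None):
        return stats.invgamma.rvs(self.a, scale=self.b, size=int(M), random_state=_as_rng(seed))


def sample_joint(prior: NormalPrior, vprior: VariancePrior, M: int, seed=None):
    """Joint draws (σ²⁽ʳ⁾, θ⁽ʳ⁾): σ² ~ IG(a, b), θ | σ² ~ N(θd, σ²/n_d).

    The drawn σ replaces the prior's nominal σ in the prior scale, so the
    effect prior inherits the variance uncertainty.
    """
    if not isinstance(prior, NormalPrior):
        raise TypeError("joint variance-effect sampling requires a NormalPrior on the effect")
    rng = _as_rng(seed)
    sigma2 = vprior.sample(int(M), rng)
    theta = rng.normal(prior.theta_d, np.sqrt(sigma2 / prior.n_d))
    return sigma2, theta


def prior_from_config(cfg: dict, sigma: float = 2.0) -> DesignPrior:
    """Build a design prior from a config mapping.

    ``cfg['type']`` selects among ``point_mass | normal | skew_normal |
    truncated_normal | mixture``; remaining keys are the prior's parameters
    (``theta_d``, ``n_d``, ``lambda``, ``theta_L``, ``theta_U``,
    ``components``+``w0``). ``sigma`` is the shared sampling SD unless the
    mapping overrides it.
    """
    cfg = dict(cfg)
    kind = cfg.pop("type", None)
    sigma = float(cfg.pop("sigma", sigma))
    try:
        if kind == "point_mass":
            return PointMassPrior(theta_d=float(cfg["theta_d"]))
        if kind == "normal":
            return NormalPrior(theta_d=float(cfg["theta_d"]), n_d=float(cfg["n_d"]), sigma=sigma)
        if kind == "skew_normal":
            return SkewNormalPrior(
                theta_d=float(cfg["theta_d"]),
                n_d=float(cfg["n_d"]),
                lam=float(cfg.get("lambda", cfg.get("lam"))),
                sigma=sigma,
            )
        if kind == "truncated_normal":
            theta_U = cfg.get("theta_U", math.inf)
            theta_U = math.inf if theta_U in (None, "inf", ".inf") else float(theta_U)
            return TruncatedNormalPrior(
                theta_d=float(cfg["theta_d"]),
                n_d=float(cfg["n_d"]),
                theta_L=float(cfg["theta_L"]),
                theta_U=theta_U,
                sigma=sigma,
            )
        if kind == "mixture":
            comps = [prior_from_config({"type": "normal", **c}, sigma=sigma) for c in cfg["components"]]
            if len(comps) != 2:
                raise ValueError("mixture config requires exactly two components")
            return MixturePrior.two_component(comps[0], comps[1], w0=float(cfg["w0"]))
    except KeyError as exc:
        raise ValueError(f"prior config missing field {exc} for type {kind!r}") from exc
    raise ValueError(f"unknown prior type {kind!r}")
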