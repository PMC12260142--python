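"""Sample-size determination from probability-of-success thresholds.

The optimal size for measure j ∈ {u, a, b, c} at threshold ε is

    n*_j = min{ n ∈ N : measure_j(n) ≥ ε },

searched with a feasibility pre-check against the n → ∞ limit: e_a and e_c
tend to p1, so their criteria are provably infeasible whenever ε ≥ p1 (no
search is attempted); u and e_b tend to 1 and are always feasible in
principle, though a finite search cap can still be hit.

The conventional threshold rule sets each ε to a common fraction of the
measure's maximum reachable value: ε_u = ε_b = fraction and
ε_a = ε_c = fraction·p1. Under that rule the e_a and e_b criteria are
equivalent (their thresholds differ by exactly the factor p1 that links
the two measures), so n*_a = n*_b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .design_priors import DesignPrior
from .pos_measures import limits, mc_estimate, quad_estimate
from .test_model import OneSidedTest

__all__ = ["SSDRequest", "SSDResult", "optimal_n", "threshold_defaults"]

MEASURES = ("u", "a", "b", "c")


@dataclass(frozen=True)
class SSDRequest:
    """One sample-size search: which measure, what threshold, which engine."""

    measure: str
    epsilon: float
    method: str = "quadrature"
    M: int = 1_000_000
    seed: int | None = None
    n_max: int = 1_000_000

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}, got {self.measure!r}")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.method not in ("quadrature", "mc"):
            raise ValueError(f"method must be 'quadrature' or 'mc', got {self.method!r}")
        if self.n_max < 1:
            raise ValueError("n_max must be positive")


@dataclass(frozen=True)
class SSDResult:
    """Outcome of one search.

    ``n_star`` is None when infeasible; ``feasible`` distinguishes a
    provable infeasibility (threshold at or above the measure's limit)
    from hitting the search cap (``at_cap``). ``trace`` records every
    (n, value) pair examined, in evaluation order, for audit.
    """

    measure: str
    epsilon: float
    n_star: int | None
    measure_at_n_star: float | None
    feasible: bool
    at_cap: bool
    limit: float
    trace: tuple[tuple[int, float], ...] = field(default=(), repr=False)


def threshold_defaults(prior: DesignPrior, fraction: float, theta0: float = 0.0) -> dict[str, float]:
    """Per-measure thresholds at a common fraction of each measure's limit.

    Returns {'u': f, 'b': f, 'a': f·p1, 'c': f·p1} with p1 the prior mass
    of the alternative.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    p1 = 1.0 - prior.prob_null(theta0)
    return {"u": fraction, "b": fraction, "a": fraction * p1, "c": fraction * p1}


def optimal_n(request: SSDRequest, test: OneSidedTest, prior: DesignPrior) -> SSDResult:
    """Minimal n whose PoS measure reaches the threshold.

    Strategy: feasibility check against the limit; exponential bracketing
    (n = 1, 2, 4, …) assuming the measure is eventually nondecreasing in
    n; bisection inside the bracket; then a short backward scan certifying
    minimality against local non-monotonicity.
    """
    lim = limits(test, prior).limit(request.measure)
    trace: list[tuple[int, float]] = []

    if request.epsilon >= lim:
        return SSDResult(
            measure=request.measure,
            epsilon=request.epsilon,
            n_star=None,
            measure_at_n_star=None,
            feasible=False,
            at_cap=False,
            limit=lim,
        )

    if request.method == "quadrature":
        def value(n: int) -> float:
            return quad_estimate(test, prior, n).measure(request.measure)
    else:
        # common random numbers: one draw set shared by every n makes the
        # estimated curve smooth in n, so the bracketing search is sound
        theta = prior.sample(request.M, request.seed)

        def value(n: int) -> float:
            import numpy as np

            from .pos_measures import _mc_from_draws

            eta = np.asarray(test.power(theta, n))
            p0 = prior.prob_null(test.theta0)
            res = _mc_from_draws(
                test, n, eta, theta > test.theta0, p0, 1.0 - p0, request.M, request.seed
            )
            return res.measure(request.measure)

    def eval_at(n: int) -> float:
        v = value(n)
        trace.append((n, v))
        return v

    # exponential bracketing
    n = 1
    v = eval_at(n)
    while v < request.epsilon:
        if n >= request.n_max:
            return SSDResult(
                measure=request.measure,
                epsilon=request.epsilon,
                n_star=None,
                measure_at_n_star=None,
                feasible=True,
                at_cap=True,
                limit=lim,
                trace=tuple(trace),
            )
        n = min(2 * n, request.n_max)
        v = eval_at(n)

    # bisection: value(lo) < epsilon <= value(hi)
    lo, hi = n // 2 if n > 1 else 0, n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if eval_at(mid) >= request.epsilon:
            hi = mid
        else:
            lo = mid

    # backward scan guards against local wiggle just below the bracket edge
    n_star = hi
    for _ in range(64):
        if n_star <= 1:
            break
        if eval_at(n_star - 1) >= request.epsilon:
            n_star -= 1
        else:
            break

    return SSDResult(
        measure=request.measure,
        epsilon=request.epsilon,
        n_star=n_star,
        measure_at_n_star=value(n_star),
        feasible=True,
        at_cap=False,
        limit=lim,
        trace=tuple(trace),
    )
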