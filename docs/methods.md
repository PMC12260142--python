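# Methods

## Decision-theoretic setup

The planned experiment is summarised by a one-sided z-test of
`H0: θ ≤ θ0` against `H1: θ > θ0` for the mean of
`X̄_n ~ Normal(θ, σ²/n)` with known σ. Under the symmetric 0–1 utility
(utility 1 for accepting the true hypothesis, 0 otherwise), the expected
utility of the test at a fixed effect is

    U_n(θ) = 1 − η_n(θ)  for θ ≤ θ0,    U_n(θ) = η_n(θ)  for θ > θ0,

the probability of the correct decision, with
`η_n(θ) = Φ(√n(θ − θ0)/σ − z_{1−α})` the power function. Averaging `U_n`
over a proper design prior π gives the Bayes utility `u = E_π[U_n(Θ)]`
(u-PoS); its complement `1 − u` is the Bayes risk of the test under 0–1
loss. Decomposing over the null/alternative masses `p0`, `p1` and the
conditional priors gives `u = p0·u0 + p1·u1` and the three classical
competitors `e_a = p1·u1`, `e_b = u1`, `e_c = p0(1 − u0) + p1·u1`
(assurance). For `p0 ∈ (0, 1)` these satisfy `u > e_a`, `e_a < e_b`,
`e_a < e_c` and `u > e_c ⇔ u0 > ½`; when `p0 = 0` all four coincide, and a
point-mass prior in the alternative reduces them all to the classical power
at the design value.

Because the z-test is size-α consistent (`η_n → 0` on the null interior, α
at θ0, 1 on the alternative), dominated convergence gives the limits
`u, e_b → 1` for any proper prior, while `e_a, e_c → p1`. The boundary
value α at θ0 does not affect the limits for continuous priors; for
point-mass priors the package places θ0 itself in the null.

## Parameters and defaults

* `theta0 = 0`, `alpha = 0.05` (one-sided), `sigma = 2` (σ² = 4). On the
  log-odds-ratio scale σ² = 4 makes `n` the effective number of events
  across both arms. These are the application's settings and the package
  defaults; all are overridable per scenario.
* Design priors are parameterised by a location `theta_d` (the design
  effect) and a prior sample size `n_d`, giving scale `σ/√n_d` — prior
  precision expressed in the same units as data information. The skew
  normal uses `σ/√n_d` as its *scale* ω (not its standard deviation); this
  reading is what reproduces the application's null masses
  (e.g. p0 = 0.06 at θd = 0.198, n_d = 46, λ = 1 via Φ(z) − 2T(z, λ)).
* The variance prior is inverse-gamma in shape–scale form, mean `b/(a−1)`;
  IG(16, 60) has mean 4 and SD ≈ 1.07. In the joint scheme a drawn σ²
  enters **both** the effect-prior scale and the power function; marginally
  `θ − θd` is then a scaled Student-t with 2a degrees of freedom, which
  supplies the exact p0. This joint-draw convention reproduces the
  unknown-variance scenario values and is consistent with the observation
  (Verdinelli's mean-only sensitivity) that the measures respond to the
  variance prior essentially through its mean — halving the prior SD at
  fixed mean moves u-PoS by well under 0.01.
* Only "greater" alternatives are implemented; a "less" direction is
  obtained by negating the effect scale on the caller's side.

## Numerical evaluation

**Monte Carlo.** All four measures are sample averages over one common set
of M prior draws (default M = 10⁶): `e_c` averages `η_n(θ⁽ʳ⁾)`, `e_a`
restricts to draws above θ0, `e_b` is the ratio estimator `e_a/p̄1` with
`p̄1` the empirical alternative mass, and `u` averages η on the alternative
draws and 1 − η on the null draws. Common draws make the four estimates
paired (their differences have far smaller variance than the estimates) and
make measure-versus-n curves smooth. Standard errors are sample-SD/√M; the
ratio estimator's SE uses the delta method. If no draw lands in the
alternative while `p1 > 0`, `e_b` is reported as NaN with a warning, never
as 0/0. Sampling is driven by numpy `default_rng(seed)`; truncated-normal
draws use scipy's inverse-CDF sampler so cost is independent of the
truncation mass; mixtures draw a component label then the component.

**Quadrature.** The deterministic route integrates `η_n·π` separately over
Ω0 and Ω1 with adaptive Gauss–Kronrod (`scipy.integrate.quad`, limit 200),
because the utility integrand kinks at θ0. Infinite tails are truncated at
location ± 10 scale; mixtures are integrated componentwise so far-apart
modes lose no accuracy. Prior masses p0, p1 come from exact CDFs (normal;
skew normal via Owen's T; truncated normal; mixtures by weighted CDFs), so
the algebraic identities linking the four measures hold to quadrature
accuracy (≤ 1e−8 in the test grid). For a normal prior, assurance also has
the closed form `e_c = 1 − Φ((θ0 − θd + σ z_{1−α}/√n)/ξd)` with
`ξd = σ√(1/n_d + 1/n)`, used as an independent cross-check of the
quadrature (agreement to 1e−8).

**Rate of convergence to the limits.** The residual `p1 − e_a(n)` is a
boundary-layer integral: for a prior with density π at θ0 it equals
`(σ/√n)·π(θ0)·[φ(z_{1−α}) + z_{1−α}Φ(z_{1−α})]` to first order —
about 3.6×10⁻³ for N(0.198, 4/46) at n = 10⁶ — so convergence is O(1/√n),
not exponential, whenever the prior touches the boundary. The unit tests
pin this closed-form rate. A related numerical caveat: beyond n ≈ 10⁸ the
layer (width σ/√n) is too narrow for the default quadrature grid and the
residual is silently under-reported; asymptotics should be read from the
`limits` function, not from quadrature at astronomically large n.

## Sample-size determination

`n*_j = min{n : measure_j(n) ≥ ε_j}`, with the conventional thresholds set
to a fraction (default 0.8) of each measure's maximum reachable value:
`ε_u = ε_b = f`, `ε_a = ε_c = f·p1`. Feasibility is decided *before*
searching: `ε ≥ limit` for measures a/c is provably infeasible and returns
immediately (distinct from hitting the search cap `n_max`). The search is
exponential bracketing (n = 1, 2, 4, …) plus bisection, which assumes the
quadrature curve is nondecreasing in n; a ≤ 64-step backward scan then
certifies local minimality. With the fraction rule the a- and b-criteria
are equivalent (`e_a = p1·e_b` and `ε_a = p1·ε_b`), so `n*_a = n*_b` row by
row — asserted numerically in the tests. Monte Carlo search re-uses one
common draw set across all n, keeping the estimated curve smooth; the
default engine for sizing is quadrature.

Near the threshold the measure curves can be very flat (slopes of order
10⁻⁴ per event for skeptical priors), so a value perturbation of 3×10⁻³
moves the crossing by tens of events. Sizes obtained by Monte Carlo can
therefore differ from the exact quadrature minimum by far more
than a few units even when the underlying curves agree to 0.005; the
deterministic engine reports the exact minimum.

## What the scenario generator does and does not emulate

Scenario inputs are scalar design parameters (θ0, α, σ², θd, n_d, λ,
truncation bounds, mixture weights), not data: the package evaluates design
operating characteristics exactly under its normal-approximation model.
Consequently the tests demonstrate internal correctness of the measures and
searches under that model; they say nothing about how well a sample log
odds ratio from a small binary trial is approximated by a normal with known
variance, about analysis-stage priors, or about interim/predictive
behaviour — all outside scope, as are two-sided hypotheses and non-0–1
utilities.

## Design choices made where the design was open

* Boundary convention: θ0 belongs to the null. Immaterial for continuous
  priors; enforced for point masses.
* `e_b` with `p1 = 0` (prior entirely in the null) is undefined and
  reported as NaN, not 0.
* Conditional priors π̃_i are first-class objects (density, CDF, exact
  integration against the parent, rejection sampling); the recombination
  `p0·π̃0 + p1·π̃1 = π` is tested pointwise.
* Reported n* is the raw minimal integer; no rounding to design multiples.
* Table-style output prints 3 decimals; machine-readable CSV/JSON keeps
  full precision and carries method, M, seed and package version on every
  row.
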