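# upos — probability of success as a Bayes utility

`upos` computes pre-experimental **probability of success (PoS)** measures
for a planned superiority trial analysed with a one-sided z-test, and the
sample sizes those measures imply. It is aimed at trial statisticians doing
hybrid frequentist–Bayesian design: the test is frequentist, but uncertainty
about the true effect is described by a proper *design prior* π(θ) used only
at the planning stage.

## The measures

For `H0: θ ≤ θ0` vs `H1: θ > θ0` with `X̄_n ~ N(θ, σ²/n)` and power
`η_n(θ) = Φ(√n(θ − θ0)/σ − z_{1−α})`, write `p0 = P(Θ ≤ θ0)` and
`p1 = 1 − p0` for the design-prior masses, and

    u0 = E[1 − η_n(Θ) | Θ ∈ Ω0]       (Bayes utility under the null)
    u1 = E[η_n(Θ) | Θ ∈ Ω1]           (Bayes utility under the alternative)

The package evaluates four summaries:

| measure | definition | n → ∞ limit |
|---------|------------|-------------|
| `u` (u-PoS) | `p0·u0 + p1·u1` — expected probability of choosing the **true** hypothesis (the Bayes 0–1 utility of the test) | 1 |
| `e_a` | `p1·u1` — joint probability of rejection and a true alternative | p1 |
| `e_b` | `u1` — conditional expected power | 1 |
| `e_c` (assurance) | `p0·(1 − u0) + p1·u1 = E[η_n(Θ)]` — marginal rejection probability | p1 |

Only `u` rewards a correct *acceptance* of H0; `e_c` counts type-I errors as
"successes" and tends to `p1 < 1` whenever the prior leaves mass on the null,
which is why sample-size rules based on `e_a`/`e_c` need a feasibility check
and why u-PoS-based sample sizes are systematically smaller when `p0` is
appreciable.

Priors available: point-mass, normal `N(θd, σ²/n_d)`, skew normal (shape λ,
CDF via Owen's T), truncated normal, two-component normal mixtures, plus an
optional inverse-gamma prior on σ². Estimation is by seeded Monte Carlo over
common prior draws, deterministic adaptive quadrature, or (for assurance
under a normal prior) the closed form
`e_c = 1 − Φ((θ0 − θd + σ z_{1−α}/√n)/ξd)`, `ξd = σ√(1/n_d + 1/n)`.

## Worked example

A trial on a log-odds-ratio scale (`θ0 = 0`, `σ² = 4`, one-sided
`α = 0.05`) with a skeptical design prior `N(0.198, 4/46)`:

```python
from upos import OneSidedTest, NormalPrior, SSDRequest, quad_estimate, optimal_n

test = OneSidedTest(theta0=0.0, alpha=0.05, sigma=2.0)
prior = NormalPrior(theta_d=0.198, n_d=46)

res = quad_estimate(test, prior, n=100)
print(f"u={res.u:.3f} e_a={res.e_a:.3f} e_b={res.e_b:.3f} "
      f"e_c={res.e_c:.3f} p0={res.p0:.2f} u0={res.u0:.3f}")
# u=0.600 e_a=0.353 e_b=0.471 e_c=0.357 p0=0.25 u0=0.985

print(optimal_n(SSDRequest(measure="u", epsilon=0.8), test, prior).n_star)  # 441
print(optimal_n(SSDRequest(measure="b", epsilon=0.8), test, prior).n_star)  # 747
```

At 100 events the chance of rejecting H0 (assurance) is only 0.357, but the
chance of reaching the *correct* conclusion is 0.600: the prior puts 25% of
its mass on the null, where the test is almost always right (`u0 = 0.985`).
Requiring 80% probability of a correct conclusion needs 441 events; the
conditional-expected-power criterion at the same threshold demands 747.

The same analysis from the shell, from a YAML scenario file:

```sh
upos compute --config scenario.yaml --out table.csv
upos ssd     --config scenario.yaml --out sizes.csv
upos curves  --config scenario.yaml --n-grid 10:2000:10 --out curves.csv
```

Each output CSV echoes the full configuration in its header comments, so a
table can be regenerated bit-for-bit from its own provenance. Exit codes:
0 success, 2 configuration error, 3 when every requested sample size was
infeasible.

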