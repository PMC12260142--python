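import pytest

from upos import (
    MixturePrior,
    NormalPrior,
    OneSidedTest,
    PointMassPrior,
    SkewNormalPrior,
    TruncatedNormalPrior,
)


@pytest.fixture(scope="session")
def ztest():
    """The application's test: H0 θ ≤ 0, one-sided α = 0.05, σ² = 4."""
    return OneSidedTest(theta0=0.0, alpha=0.05, sigma=2.0)


def make_mixture(w0: float) -> MixturePrior:
    """Bimodal consensus prior: w0·N(0, 4/165) + (1−w0)·N(0.545, 4/46)."""
    return MixturePrior.two_component(NormalPrior(0.0, 165), NormalPrior(0.545, 46), w0)


@pytest.fixture(scope="session")
def prior_catalog():
    """A representative prior from each family in the application."""
    return {
        "point_mass": PointMassPrior(0.372),
        "normal": NormalPrior(0.198, 46),
        "skew_normal": SkewNormalPrior(0.198, 46, lam=1.0),
        "truncated_normal": TruncatedNormalPrior(0.198, 46, theta_L=0.0),
        "mixture": make_mixture(0.5),
    }
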