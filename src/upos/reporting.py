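"""Scenario configs, batch computation and table export.

A scenario config is a plain mapping (usually loaded from YAML) with four
blocks::

    test:        {theta0: 0.0, alpha: 0.05, sigma2: 4.0}
    priors:      [{name: skeptical, type: normal, theta_d: 0.198, n_d: 46}, ...]
    evaluation:  {n: [100, 500], method: quadrature, M: 1000000, seed: 20260921}
    ssd:         {fraction: 0.8, measures: [u, a, b, c], method: quadrature,
                  n_max: 1000000}   # or thresholds: {u: 0.8, ...}
    curves:      {n_grid: [10, 20, ...]}   # or "start:stop:step"

``run_compute`` produces one row of PoS measures per (prior, n);
``run_ssd`` one row per (prior, measure); ``run_curves`` a long-format
(prior, measure, n, value) table including the frequentist power curve at
each prior's location. Every exported file echoes the config verbatim in
its ``#``-comment header so a run can be reproduced from its own output.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np
import pandas as pd

from . import __version__
from .design_priors import (
    DesignPrior,
    MixturePrior,
    NormalPrior,
    PointMassPrior,
    SkewNormalPrior,
    TruncatedNormalPrior,
    VariancePrior,
    prior_from_config,
)
from .pos_measures import (
    limits,
    mc_estimate,
    measures_with_variance_prior,
    quad_estimate,
)
from .ssd import SSDRequest, optimal_n, threshold_defaults
from .test_model import OneSidedTest

__all__ = [
    "ConfigError",
    "load_config",
    "parse_test",
    "parse_priors",
    "run_compute",
    "run_ssd",
    "run_curves",
    "write_table",
    "read_config_echo",
    "parse_n_grid",
]

log = logging.getLogger("upos")


class ConfigError(ValueError):
    """Invalid or missing configuration field; carries the field path."""


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def parse_test(cfg: dict) -> OneSidedTest:
    block = cfg.get("test", {})
    try:
        sigma2 = float(block.get("sigma2", 4.0))
        if sigma2 <= 0:
            raise ConfigError("test.sigma2: must be positive")
        return OneSidedTest(
            theta0=float(block.get("theta0", 0.0)),
            alpha=float(block.get("alpha", 0.05)),
            sigma=math.sqrt(sigma2),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"test: {exc}") from exc


def _prior_label(pcfg: dict) -> str:
    if "name" in pcfg:
        return str(pcfg["name"])
    kind = pcfg.get("type", "?")
    if kind == "mixture":
        return f"mixture(w0={pcfg.get('w0')})"
    bits = [str(pcfg.get("theta_d"))]
    if "n_d" in pcfg:
        bits.append(str(pcfg["n_d"]))
    return f"{kind}({', '.join(bits)})"


def parse_priors(cfg: dict, sigma: float) -> list[tuple[str, DesignPrior, VariancePrior | None]]:
    """Build (label, prior, optional variance prior) triples from config."""
    blocks = cfg.get("priors")
    if not blocks:
        raise ConfigError("priors: at least one prior block is required")
    out = []
    for i, pcfg in enumerate(blocks):
        try:
            vp_cfg = pcfg.get("variance_prior")
            vprior = VariancePrior(a=float(vp_cfg["a"]), b=float(vp_cfg["b"])) if vp_cfg else None
            prior = prior_from_config({k: v for k, v in pcfg.items() if k not in ("name", "variance_prior")}, sigma=sigma)
            if vprior is not None and not isinstance(prior, NormalPrior):
                raise ConfigError(f"priors[{i}].variance_prior: only supported with a normal prior")
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"priors[{i}]: {exc}") from exc
        out.append((_prior_label(pcfg), prior, vprior))
    return out


def _provenance(method: str, M, seed) -> dict:
    return {
        "method": method,
        "M": M if method == "mc" else None,
        "seed": seed if method == "mc" else None,
        "version": __version__,
    }


def run_compute(cfg: dict) -> pd.DataFrame:
    """One row of all four PoS measures per (prior, n)."""
    test = parse_test(cfg)
    priors = parse_priors(cfg, test.sigma)
    ev = cfg.get("evaluation", {})
    n_list = ev.get("n", [])
    method = ev.get("method", "quadrature")
    if method not in ("quadrature", "mc"):
        raise ConfigError(f"evaluation.method: unknown method {method!r}")
    M = int(ev.get("M", 1_000_000))
    seed = ev.get("seed")

    rows = []
    for label, prior, vprior in priors:
        for n in n_list:
            if vprior is not None:
                res = measures_with_variance_prior(test, prior, vprior, int(n), M=M, seed=seed)
            elif method == "mc":
                res = mc_estimate(test, prior, int(n), M=M, seed=seed)
            else:
                res = quad_estimate(test, prior, int(n))
            log.debug(
                "%s n=%d: u=%.4f e_a=%.4f e_b=%.4f e_c=%.4f (SE u=%s)",
                label, int(n), res.u, res.e_a, res.e_b, res.e_c, res.se_u,
            )
            rows.append({"prior": label, **res.to_dict(), "version": __version__})
    cols = [
        "prior", "p0", "p1", "n", "e_a", "e_b", "e_c", "u", "u0", "u1",
        "method", "M", "seed", "se_u", "se_a", "se_b", "se_c", "version",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_ssd(cfg: dict) -> pd.DataFrame:
    """Optimal sample size per (prior, measure) with feasibility flags."""
    test = parse_test(cfg)
    priors = parse_priors(cfg, test.sigma)
    block = cfg.get("ssd", {})
    measures = block.get("measures", ["u", "a", "b", "c"])
    method = block.get("method", "quadrature")
    M = int(block.get("M", 1_000_000))
    seed = block.get("seed")
    n_max = int(block.get("n_max", 1_000_000))
    explicit = block.get("thresholds")
    fraction = block.get("fraction")
    if explicit is None and fraction is None:
        raise ConfigError("ssd: provide either 'fraction' or explicit 'thresholds'")

    rows = []
    for label, prior, _vprior in priors:
        eps_map = (
            dict(explicit)
            if explicit is not None
            else threshold_defaults(prior, float(fraction), theta0=test.theta0)
        )
        for m in measures:
            if m not in eps_map:
                raise ConfigError(f"ssd.thresholds: missing threshold for measure {m!r}")
            req = SSDRequest(
                measure=m, epsilon=float(eps_map[m]), method=method, M=M, seed=seed, n_max=n_max
            )
            res = optimal_n(req, test, prior)
            if not res.feasible:
                log.warning(
                    "%s measure=%s: infeasible (threshold %.4f >= limit %.4f)",
                    label, m, res.epsilon, res.limit,
                )
            rows.append(
                {
                    "prior": label,
                    "p0": prior.prob_null(test.theta0),
                    "measure": m,
                    "epsilon": res.epsilon,
                    "n_star": res.n_star,
                    "measure_at_n_star": res.measure_at_n_star,
                    "feasible": res.feasible,
                    "at_cap": res.at_cap,
                    "limit": res.limit,
                    **_provenance(method, M, seed),
                }
            )
    return pd.DataFrame(rows)


def run_curves(cfg: dict, n_grid=None) -> pd.DataFrame:
    """Long-format (prior, measure, n, value) table for curve plotting.

    Alongside u, e_a, e_b, e_c the table carries the frequentist power
    η_n(θd) evaluated at each prior's location ('power' rows), the curve a
    conditional power analysis would report.
    """
    test = parse_test(cfg)
    priors = parse_priors(cfg, test.sigma)
    if n_grid is None:
        n_grid = parse_n_grid(cfg.get("curves", {}).get("n_grid"))
    rows = []
    for label, prior, _vprior in priors:
        theta_d = getattr(prior, "theta_d", None)
        for n in n_grid:
            res = quad_estimate(test, prior, int(n))
            for m_name, val in (("u", res.u), ("e_a", res.e_a), ("e_b", res.e_b), ("e_c", res.e_c)):
                rows.append({"prior": label, "measure": m_name, "n": int(n), "value": val})
            if theta_d is not None:
                rows.append(
                    {
                        "prior": label,
                        "measure": "power",
                        "n": int(n),
                        "value": float(test.power(theta_d, int(n))),
                    }
                )
    df = pd.DataFrame(rows, columns=["prior", "measure", "n", "value"])
    df["version"] = __version__
    return df


def parse_n_grid(spec) -> list[int]:
    """An explicit list, or a 'start:stop:step' string (stop inclusive)."""
    if spec is None:
        raise ConfigError("curves.n_grid: an n grid is required")
    if isinstance(spec, str):
        try:
            start, stop, step = (int(s) for s in spec.split(":"))
        except ValueError as exc:
            raise ConfigError(f"curves.n_grid: expected 'start:stop:step', got {spec!r}") from exc
        if start < 1 or step < 1 or stop < start:
            raise ConfigError(f"curves.n_grid: invalid range {spec!r}")
        return list(range(start, stop + 1, step))
    return [int(n) for n in spec]


def write_table(df: pd.DataFrame, path, cfg: dict) -> None:
    """Write CSV with the scenario config echoed in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# upos {__version__}\n")
        fh.write("# config: " + json.dumps(cfg, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_config_echo(path) -> dict:
    """Recover the config a table was produced from (round-trip support)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# config: "):
                return json.loads(line[len("# config: "):])
    raise ConfigError(f"{path}: no config echo header found")
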