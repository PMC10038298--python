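"""MCMC fitting, posterior summaries, HPD intervals, and round comparison."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConsumptionMatrix, RegionParams
from .priors import PriorSpec
from .sampler import run_chain

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "hpd",
    "summarize",
    "compare_rounds",
    "ConsumptionResults",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler protocol: defaults are 4 chains of 4000 steps, 1000 burn-in."""

    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (0 <= self.warmup < self.iterations):
            raise ValueError("need 0 <= warmup < iterations")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with dims (chain, draw, ...)."""

    p: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    Omega: np.ndarray
    logpost: np.ndarray
    group_names: list[str]

    def __post_init__(self):
        C, T, J = self.p.shape
        if self.Omega.shape != (C, T, J, J):
            raise ValueError("Omega draws have inconsistent shape")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("p draws must lie in (0, 1)")
        if np.any(self.theta <= 0) or np.any(self.sigma < 0):
            raise ValueError("theta draws must be positive, sigma non-negative")

    @property
    def n_chains(self) -> int:
        return self.p.shape[0]

    @property
    def n_draws(self) -> int:
        return self.p.shape[0] * self.p.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one block with chains stacked along the first axis."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def labelled(self) -> dict[str, np.ndarray]:
        """Flat map from parameter label to (chain, draw) arrays."""
        g = self.group_names
        out = {}
        for j, name in enumerate(g):
            out[f"p[{name}]"] = self.p[:, :, j]
            out[f"theta[{name}]"] = self.theta[:, :, j]
            out[f"sigma[{name}]"] = self.sigma[:, :, j]
        for j in range(len(g)):
            for k in range(j + 1, len(g)):
                out[f"Omega[{g[j]},{g[k]}]"] = self.Omega[:, :, j, k]
        return out

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.labelled().items()})

    def to_csv(self, path) -> None:
        """Flat draw table: chain, iter, parameter, value."""
        rows = []
        for label, arr in self.labelled().items():
            C, T = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(C), T),
                "iter": np.tile(np.arange(T), C),
                "parameter": label,
                "value": arr.ravel(),
            }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def hpd(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Computed by exhaustive search over windows of the sorted sample, so it is
    the minimal-width interval among all windows holding at least
    ``ceil(mass * n)`` draws.
    """
    x = np.sort(np.asarray(draws).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


class PosteriorSummary:
    """Posterior mean, 95% HPD bounds, and diagnostics per parameter."""

    def __init__(self, table: pd.DataFrame, hpd_mass: float = 0.95):
        self.table = table
        self.hpd_mass = hpd_mass

    def __repr__(self):
        return self.table.to_string(float_format=lambda v: f"{v:.3f}")

    def row(self, label: str) -> pd.Series:
        return self.table.loc[label]

    def to_json(self, path, region: str = "region") -> None:
        payload = {region: {
            label: {
                "mean": float(r["mean"]),
                "hpd_lower": float(r["hpd_lower"]),
                "hpd_upper": float(r["hpd_upper"]),
            }
            for label, r in self.table.iterrows()
        }}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def summarize(draws: PosteriorDraws, hpd_mass: float = 0.95,
              diagnostics: bool = True) -> PosteriorSummary:
    """Posterior mean and HPD interval for every parameter.

    Adds split-R̂ and bulk effective sample size when ``diagnostics`` is on;
    values beyond R̂ > 1.05 or ESS < 100 are logged as warnings, not errors.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    labelled = draws.labelled()
    rhat_map, ess_map = {}, {}
    if diagnostics and draws.n_chains >= 2:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = draws.to_inference_data()
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        for label in labelled:
            rhat_map[label] = float(rhat[label].values)
            ess_map[label] = float(ess[label].values)

    recs = []
    for label, arr in labelled.items():
        lo, hi = hpd(arr, hpd_mass)
        rec = {
            "parameter": label,
            "mean": float(arr.mean()),
            "hpd_lower": lo,
            "hpd_upper": hi,
        }
        if label in rhat_map:
            rec["rhat"] = rhat_map[label]
            rec["ess"] = ess_map[label]
            if np.isfinite(rec["rhat"]) and rec["rhat"] > 1.05:
                logger.warning("split-Rhat %.3f > 1.05 for %s", rec["rhat"], label)
            if np.isfinite(rec["ess"]) and rec["ess"] < 100:
                logger.warning("effective sample size %.0f < 100 for %s", rec["ess"], label)
        recs.append(rec)
    table = pd.DataFrame(recs).set_index("parameter")
    return PosteriorSummary(table, hpd_mass)


def compare_rounds(summary_a: PosteriorSummary, summary_b: PosteriorSummary) -> pd.DataFrame:
    """Flag parameters whose 95% HPD intervals do not overlap across rounds.

    Returns a table with a ``change`` column: "increase" / "decrease" when
    the intervals are disjoint (direction from their ordering), else
    "no evidence".
    """
    a, b = summary_a.table, summary_b.table
    if set(a.index) != set(b.index):
        raise ValueError("summaries cover different parameter sets")
    rows = []
    for label in a.index:
        lo_a, hi_a = a.loc[label, "hpd_lower"], a.loc[label, "hpd_upper"]
        lo_b, hi_b = b.loc[label, "hpd_lower"], b.loc[label, "hpd_upper"]
        if lo_b > hi_a:
            change = "increase"
        elif hi_b < lo_a:
            change = "decrease"
        else:
            change = "no evidence"
        rows.append({
            "parameter": label,
            "interval_a": (lo_a, hi_a),
            "interval_b": (lo_b, hi_b),
            "change": change,
        })
    return pd.DataFrame(rows).set_index("parameter")


def fit(
    data: ConsumptionMatrix,
    priors: PriorSpec,
    config: McmcConfig,
    fixed: dict | None = None,
    progress: bool = False,
) -> "ConsumptionResults":
    """Fit the hierarchical model by MCMC and wrap the draws in a Results object."""
    if data.n_households < 1:
        raise ValueError("empty data")
    if priors.J != data.n_groups:
        raise ValueError("prior dimension does not match data")
    chains = []
    for c in range(config.chains):
        rng = np.random.default_rng([config.seed, c])
        chains.append(run_chain(
            data.counts, data.m, priors,
            iterations=config.iterations, warmup=config.warmup,
            rng=rng, fixed=fixed,
        ))
        if progress:
            logger.info("chain %d/%d done", c + 1, config.chains)
    draws = PosteriorDraws(
        p=np.stack([c["p"] for c in chains]),
        theta=np.stack([c["theta"] for c in chains]),
        sigma=np.stack([c["sigma"] for c in chains]),
        Omega=np.stack([c["Omega"] for c in chains]),
        logpost=np.stack([c["logpost"] for c in chains]),
        group_names=list(data.group_names),
    )
    return ConsumptionResults(data=data, priors=priors, config=config, draws=draws)


@dataclass
class ConsumptionResults:
    """Fitted-model object: draws, summaries, simulation, and comparisons."""

    data: ConsumptionMatrix
    priors: PriorSpec
    config: McmcConfig
    draws: PosteriorDraws
    _summary: PosteriorSummary | None = field(default=None, repr=False)

    def summary(self, hpd_mass: float = 0.95) -> PosteriorSummary:
        if self._summary is None or self._summary.hpd_mass != hpd_mass:
            self._summary = summarize(self.draws, hpd_mass)
        return self._summary

    def posterior_mean_params(self) -> RegionParams:
        """Posterior-mean parameter set (mean Omega stays a valid correlation)."""
        Om = self.draws.stacked("Omega").mean(0)
        d = np.sqrt(np.diag(Om))
        Om = Om / np.outer(d, d)
        return RegionParams(
            group_names=list(self.data.group_names),
            p=np.clip(self.draws.stacked("p").mean(0), 1e-6, 1 - 1e-6),
            theta=self.draws.stacked("theta").mean(0),
            sigma=self.draws.stacked("sigma").mean(0),
            Omega=Om,
            m=self.data.m,
            region=self.data.region,
        )

    def simulate(self, n_sim: int = 12000, seed=None, mode: str = "integrated",
                 decorrelated: bool = False) -> ConsumptionMatrix:
        """Posterior-predictive survey simulation.

        ``mode="integrated"`` draws one posterior sample per simulated
        household (propagating posterior uncertainty); ``mode="mean"``
        simulates from the posterior-mean parameters.
        """
        from . import gof as _gof

        rng = np.random.default_rng(seed)
        if mode == "mean":
            params = self.posterior_mean_params()
            sim = (_gof.simulate_decorrelated if decorrelated
                   else _gof.simulate_households)
            return sim(params, n_sim, rng)
        if mode != "integrated":
            raise ValueError("mode must be 'integrated' or 'mean'")
        return _gof.simulate_posterior_predictive(
            self.draws, n_sim, rng, m=self.data.m,
            region=self.data.region, decorrelated=decorrelated,
        )

    def gof(self, scheme=None, n_sim: int = 12000, seed=None,
            mode: str = "integrated"):
        """Posterior-predictive goodness-of-fit report against the fitted data."""
        from . import gof as _gof
        from .indicators import default_yemen_scheme

        if scheme is None:
            scheme = default_yemen_scheme(self.data.group_names)
        simulated = self.simulate(n_sim=n_sim, seed=seed, mode=mode)
        return _gof.gof_report(self.data, simulated, scheme)

    def compare(self, other: "ConsumptionResults") -> pd.DataFrame:
        """HPD-overlap change table against another fitted round."""
        return compare_rounds(self.summary(), other.summary())

    def baseline_summary(self):
        """Condense this fit into the statistics a follow-up round needs."""
        from .updating import BaselineSummary

        return BaselineSummary.from_results(self)

    def plot_fcs_density(self, scheme=None, n_sim: int = 12000, seed=None, ax=None):
        """Kernel-density plot of observed vs simulated FCS distributions."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        from .indicators import compute_indicators, default_yemen_scheme

        if scheme is None:
            scheme = default_yemen_scheme(self.data.group_names)
        obs = compute_indicators(self.data, scheme)["fcs"].to_numpy()
        sim_m = self.simulate(n_sim=n_sim, seed=seed)
        sim = compute_indicators(sim_m, scheme)["fcs"].to_numpy()
        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 112, 300)
        ax.plot(grid, gaussian_kde(obs)(grid), label="observed")
        ax.plot(grid, gaussian_kde(sim)(grid), label="simulated")
        ax.set_xlabel("FCS")
        ax.set_ylabel("density")
        ax.legend()
        return ax
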