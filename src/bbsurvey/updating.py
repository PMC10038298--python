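"""Weighted prior updating between survey rounds, and planning tools.

A comprehensive baseline survey yields narrow posteriors: under a uniform
prior and a binomial likelihood the daily probability p_0j has the conjugate
posterior Beta(1 + S, 1 + 7 n0 - S) with S the total consumption days, whose
standard deviation is below 0.02 already at n0 = 100.  Used directly as a
prior for a smaller emergency round this would swamp the new data, so the
carried-forward priors are power-weighted:

    p_j     ~ Beta(a * phat0_j, a * (1 - phat0_j))       (prior weight a)
    theta_j ~ Gamma(alpha_w * thetahat0_j, alpha_w)      (weight alpha_w)
    rho_jk  ~ Normal(rhohat0_jk, 1) truncated to (-1, 1)
    sigma_j ~ Half-Cauchy(0, 2)                          (unchanged)

The planning tools quantify what a choice of weights implies for the
follow-up posterior: a closed-form mean/variance for p from the conjugate
update, and a normal approximation to the joint (p, theta) posterior via its
mode and inverse Hessian, accurate for follow-up samples of n_d >= 250.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from .containers import ConsumptionMatrix
from .priors import (
    BetaPrior,
    GammaPrior,
    HalfCauchyPrior,
    PriorSpec,
    TruncNormCorrPrior,
)

__all__ = [
    "BaselineSummary",
    "UpdateWeights",
    "baseline_beta_posterior",
    "make_updated_priors",
    "updated_beta_moments",
    "normal_approx_posterior",
    "planning_halfwidth_p",
    "planning_halfwidths",
]


@dataclass(frozen=True)
class UpdateWeights:
    """Prior weights: ``a`` for the proportions, ``alpha_w`` for dispersions."""

    a: float = 50.0
    alpha_w: float = 5.0

    def __post_init__(self):
        if self.a <= 0 or self.alpha_w <= 0:
            raise ValueError("weights must be positive")


@dataclass
class BaselineSummary:
    """Condensed baseline fit used to build follow-up priors."""

    n0: int
    group_names: list[str]
    phat0: np.ndarray
    theta_hat0: np.ndarray
    sigma_hat0: np.ndarray
    rho_hat0: np.ndarray

    def __post_init__(self):
        self.phat0 = np.asarray(self.phat0, float)
        self.theta_hat0 = np.asarray(self.theta_hat0, float)
        self.sigma_hat0 = np.asarray(self.sigma_hat0, float)
        self.rho_hat0 = np.asarray(self.rho_hat0, float)
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if np.any((self.phat0 < 0) | (self.phat0 > 1)):
            raise ValueError("phat0 must lie in [0, 1]")
        if np.any(self.theta_hat0 <= 0):
            raise ValueError("theta_hat0 must be positive")

    @classmethod
    def from_results(cls, results) -> "BaselineSummary":
        """Build from a fitted baseline round.

        The proportions are the baseline *sample* proportions (sum of days
        over 7 n0); dispersion, sigma, and correlation carry the posterior
        means.
        """
        data = results.data
        params = results.posterior_mean_params()
        phat0 = data.counts.sum(0) / (data.m * data.n_households)
        return cls(
            n0=data.n_households,
            group_names=list(data.group_names),
            phat0=phat0,
            theta_hat0=params.theta,
            sigma_hat0=params.sigma,
            rho_hat0=params.Omega,
        )

    def to_json(self, path, region: str = "region") -> None:
        with open(path, "w") as fh:
            json.dump({region: {
                "n0": int(self.n0),
                "group_names": list(self.group_names),
                "phat0": self.phat0.tolist(),
                "theta_hat0": self.theta_hat0.tolist(),
                "sigma_hat0": self.sigma_hat0.tolist(),
                "rho_hat0": self.rho_hat0.tolist(),
            }}, fh, indent=1)

    @classmethod
    def from_json(cls, path, region: str | None = None) -> "BaselineSummary":
        with open(path) as fh:
            payload = json.load(fh)
        if region is None:
            region = next(iter(payload))
        d = payload[region]
        return cls(n0=d["n0"], group_names=d["group_names"],
                   phat0=d["phat0"], theta_hat0=d["theta_hat0"],
                   sigma_hat0=d["sigma_hat0"], rho_hat0=d["rho_hat0"])


def baseline_beta_posterior(n0: int, phat0: float) -> dict:
    """Conjugate Beta posterior of the daily probability after the baseline.

    Under a uniform prior and binomial likelihood over 7 n0 household-days,
    the posterior is Beta(1 + 7 n0 phat0, 1 + 7 n0 (1 - phat0)).  Returns
    the shapes together with the exact mean and standard deviation.
    """
    if n0 < 1 or not 0 <= phat0 <= 1:
        raise ValueError("need n0 >= 1 and phat0 in [0, 1]")
    s = 7.0 * n0 * phat0
    a = 1.0 + s
    b = 1.0 + 7.0 * n0 - s
    mean = a / (a + b)
    var = mean * (1.0 - mean) / (a + b + 1.0)
    return {"a": a, "b": b, "mean": mean, "sd": float(np.sqrt(var))}


def make_updated_priors(base: BaselineSummary, weights: UpdateWeights = UpdateWeights(),
                        corr_sd: float = 1.0) -> PriorSpec:
    """Weighted informative priors for the follow-up round.

    Degenerate baseline proportions (exactly 0 or 1) are clamped to
    eps = 1/(7 n0 + 2), matching the resolution of the conjugate posterior
    mean, with a logged warning.
    """
    import logging

    eps = 1.0 / (7.0 * base.n0 + 2.0)
    phat = base.phat0.copy()
    bad = (phat <= 0) | (phat >= 1)
    if np.any(bad):
        logging.getLogger(__name__).warning(
            "clamping %d degenerate baseline proportion(s) to [%g, %g]",
            int(bad.sum()), eps, 1 - eps)
        phat = np.clip(phat, eps, 1 - eps)
    J = len(base.group_names)
    rho = np.clip(base.rho_hat0.copy(), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return PriorSpec(
        p=[BetaPrior(weights.a * phat[j], weights.a * (1 - phat[j])) for j in range(J)],
        theta=[GammaPrior(weights.alpha_w * base.theta_hat0[j], weights.alpha_w)
               for j in range(J)],
        sigma=[HalfCauchyPrior(2.0) for _ in range(J)],
        Omega=TruncNormCorrPrior(means=rho, sd=corr_sd),
    )


def updated_beta_moments(phat0: float, a: float, nd: int, phat_d: float) -> tuple[float, float]:
    """Closed-form approximate posterior mean and variance of the updated p.

    mean = (a phat0 + 7 nd phat_d)/(a + 7 nd): a convex combination of the
    baseline and follow-up proportions with weight a/(a + 7 nd) on the prior.
    """
    if not (0 <= phat0 <= 1 and 0 <= phat_d <= 1) or a <= 0 or nd < 1:
        raise ValueError("invalid arguments")
    denom = a + 7.0 * nd
    mean = (a * phat0 + 7.0 * nd * phat_d) / denom
    comp = (a * (1 - phat0) + 7.0 * nd * (1 - phat_d)) / denom
    var = mean * comp / (denom + 1.0)
    return float(mean), float(var)


def _weighted_loglik(w, logC, ys, m, p, theta):
    a = p * theta
    b = (1 - p) * theta
    ll = (logC + gammaln(ys + a) + gammaln(m - ys + b) - gammaln(m + a + b)
          - gammaln(a) - gammaln(b) + gammaln(a + b))
    return float(np.sum(w * ll))


def normal_approx_posterior(phat0: float, theta_hat0: float,
                            weights: UpdateWeights,
                            counts=None, scenario: tuple | None = None,
                            nd: int | None = None, m: int = 7) -> dict:
    """Normal approximation to the joint (p, theta) posterior of one group.

    The single-group model here is the marginal beta-binomial without random
    effects (the planning model).  Data enter either as actual ``counts`` or
    as a ``scenario`` pair (p_d, theta_d) with sample size ``nd``, in which
    case the expected cell counts nd * P(y) replace the observed tally —
    the deterministic planning version.

    The mode of log prior + log likelihood is found numerically over
    (logit p, log theta); the covariance is the inverse central-difference
    Hessian at the mode (step 1e-4 on the transformed scales), mapped back
    to (p, theta) by the delta method.  Returns mode, covariance, and 95%
    half-widths 1.96 * sqrt(diag).
    """
    ys = np.arange(m + 1, dtype=float)
    logC = gammaln(m + 1) - gammaln(ys + 1) - gammaln(m - ys + 1)
    if counts is not None:
        counts = np.asarray(counts)
        w = np.array([(counts == y).sum() for y in range(m + 1)], dtype=float)
        x0 = np.array([np.clip(counts.mean() / m, 0.02, 0.98), theta_hat0])
    elif scenario is not None:
        if nd is None or nd < 1:
            raise ValueError("scenario mode needs nd >= 1")
        p_d, theta_d = scenario
        a, b = p_d * theta_d, (1 - p_d) * theta_d
        ll = (logC + gammaln(ys + a) + gammaln(m - ys + b) - gammaln(m + a + b)
              - gammaln(a) - gammaln(b) + gammaln(a + b))
        w = nd * np.exp(ll)
        x0 = np.array([p_d, theta_d])
    else:
        raise ValueError("provide counts or a scenario")

    ap, bp = weights.a * phat0, weights.a * (1 - phat0)
    ath, rth = weights.alpha_w * theta_hat0, weights.alpha_w

    def neg_logpost_z(z):
        p = expit(z[0])
        th = np.exp(z[1])
        ll = _weighted_loglik(w, logC, ys, m, p, th)
        lp = (ap - 1) * np.log(p) + (bp - 1) * np.log1p(-p)
        lth = (ath - 1) * np.log(th) - rth * th
        return -(ll + lp + lth)

    z0 = np.array([np.log(x0[0] / (1 - x0[0])), np.log(x0[1])])
    res = minimize(neg_logpost_z, z0, method="BFGS", options=dict(gtol=1e-9))
    if not res.success:  # polish / rescue with a simplex search
        res = minimize(neg_logpost_z, res.x, method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-11, maxiter=20000))
    if not res.success:
        raise RuntimeError(f"posterior mode search failed: {res.message}")
    z = res.x

    h = 1e-4
    H = np.zeros((2, 2))
    f0 = neg_logpost_z(z)
    e = np.eye(2)
    for i in range(2):
        H[i, i] = (neg_logpost_z(z + h * e[i]) - 2 * f0
                   + neg_logpost_z(z - h * e[i])) / (h * h)
    H[0, 1] = H[1, 0] = (
        neg_logpost_z(z + h * (e[0] + e[1]))
        - neg_logpost_z(z + h * (e[0] - e[1]))
        - neg_logpost_z(z - h * (e[0] - e[1]))
        + neg_logpost_z(z - h * (e[0] + e[1]))
    ) / (4 * h * h)
    eig = np.linalg.eigvalsh(H)
    if np.any(eig <= 0):
        raise RuntimeError("Hessian at the mode is not positive definite")
    cov_z = np.linalg.inv(H)
    p_mode, th_mode = float(expit(z[0])), float(np.exp(z[1]))
    Jac = np.diag([p_mode * (1 - p_mode), th_mode])
    cov = Jac @ cov_z @ Jac
    half = 1.96 * np.sqrt(np.diag(cov))
    return {
        "mode": (p_mode, th_mode),
        "cov": cov,
        "halfwidth_p": float(half[0]),
        "halfwidth_theta": float(half[1]),
    }


def planning_halfwidth_p(a: float = 50.0, nd: int = 360,
                         grid_points: int = 101) -> float:
    """Maximum 95% half-width for the updated p over all proportion pairs.

    Uses the closed-form updated Beta posterior variance, maximized over a
    dense grid of baseline and follow-up proportions.  This is the planning
    bound used to choose the weight ``a``; it does not depend on theta.
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    worst = 0.0
    for p0 in grid:
        for pd_ in grid:
            _, var = updated_beta_moments(p0, a, nd, pd_)
            worst = max(worst, 1.96 * float(np.sqrt(var)))
    return worst


def planning_halfwidths(weights: UpdateWeights = UpdateWeights(), nd: int = 360,
                        p_grid=None, theta_grid=None, dp_grid=(-0.1, 0.0, 0.1)) -> dict:
    """Normal-approximation half-widths over a (phat0, theta0, phat_d) grid.

    Returns the maxima of the p and theta half-widths from the joint
    normal approximation; used for the +/- 2.2 theta planning bound.
    """
    if p_grid is None:
        p_grid = np.linspace(0.05, 0.95, 10)
    if theta_grid is None:
        theta_grid = (1.0, 2.0, 5.0, 10.0)
    worst_p = worst_t = 0.0
    for p0 in p_grid:
        for th in theta_grid:
            for dp in dp_grid:
                p_d = float(np.clip(p0 + dp, 0.02, 0.98))
                res = normal_approx_posterior(p0, th, weights,
                                              scenario=(p_d, th), nd=nd)
                worst_p = max(worst_p, res["halfwidth_p"])
                worst_t = max(worst_t, res["halfwidth_theta"])
    return {"max_halfwidth_p": worst_p, "max_halfwidth_theta": worst_t}
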