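"""Reparametrized beta-binomial distribution and the logit-shift link.

The beta-binomial used throughout this package is parametrized by the mean
daily probability ``p`` and a dispersion parameter ``theta``: conditional on
a latent success probability ``q ~ Beta(p*theta, (1-p)*theta)`` the count is
``Binomial(m, q)``.  Small ``theta`` means strong overdispersion (mass piling
up at 0 and m); as ``theta`` grows the distribution converges to the plain
``Binomial(m, p)``.  In the weekly food-consumption setting ``m = 7`` and a
count is the number of days in the recall week a household consumed a food
group.  Beyond roughly ``theta > 50`` the beta-binomial is operationally
indistinguishable from the binomial at ``m = 7``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logit

__all__ = [
    "BetaBinParams",
    "betabin_logpmf",
    "betabin_pmf",
    "betabin_moments",
    "betabin_sample",
    "gamma_link",
]


@dataclass(frozen=True)
class BetaBinParams:
    """Parameters of the mean/dispersion beta-binomial.

    Attributes
    ----------
    m : int
        Number of trials (days in the recall window), ``m >= 1``.
    p : float
        Mean daily consumption probability, strictly in (0, 1).
    theta : float
        Dispersion, strictly positive.  The implied classical shapes are
        ``alpha = p * theta`` and ``beta = (1 - p) * theta``.
    """

    m: int
    p: float
    theta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"m must be an integer >= 1, got {self.m!r}")
        if not (np.isfinite(self.p) and 0.0 < self.p < 1.0):
            raise ValueError(f"p must be finite and in (0, 1), got {self.p!r}")
        if not (np.isfinite(self.theta) and self.theta > 0.0):
            raise ValueError(f"theta must be finite and > 0, got {self.theta!r}")

    @property
    def alpha(self) -> float:
        return self.p * self.theta

    @property
    def beta(self) -> float:
        return (1.0 - self.p) * self.theta


def _logpmf_arrays(y, m, p, theta):
    """Log pmf via log-gamma differences; broadcasts over all arguments."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(p, dtype=float) * theta
    b = (1.0 - np.asarray(p, dtype=float)) * theta
    return (
        gammaln(m + 1.0)
        - gammaln(y + 1.0)
        - gammaln(m - y + 1.0)
        + gammaln(y + a)
        + gammaln(m - y + b)
        - gammaln(m + a + b)
        - gammaln(a)
        - gammaln(b)
        + gammaln(a + b)
    )


def betabin_logpmf(y, params: BetaBinParams):
    """Log probability of count ``y`` (scalar or array) under ``params``."""
    y_arr = np.asarray(y)
    if not np.issubdtype(y_arr.dtype, np.number):
        raise ValueError("y must be numeric")
    if np.any(y_arr < 0) or np.any(y_arr > params.m) or np.any(y_arr != np.floor(y_arr)):
        raise ValueError(f"y must be an integer in [0, {params.m}]")
    out = _logpmf_arrays(y_arr, params.m, params.p, params.theta)
    return out if out.shape else float(out)


def betabin_pmf(y, params: BetaBinParams):
    """Probability mass of count ``y`` under ``params``.

    Computed as exp of the log-gamma expression
    ``C(m, y) * B(y + alpha, m - y + beta) / B(alpha, beta)`` for numerical
    stability at large ``theta``.
    """
    return np.exp(betabin_logpmf(y, params))


def betabin_moments(params: BetaBinParams) -> tuple[float, float]:
    """Mean and variance: ``m p`` and ``m p (1-p) (1 + (m-1)/(theta+1))``."""
    m, p, theta = params.m, params.p, params.theta
    mean = m * p
    var = m * p * (1.0 - p) * (1.0 + (m - 1.0) / (theta + 1.0))
    return mean, var


def betabin_sample(params: BetaBinParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` counts by compositional sampling.

    Draws ``q ~ Beta(p theta, (1-p) theta)`` then ``Binomial(m, q)``, which is
    exact for the mean/dispersion parametrization.

    Parameters
    ----------
    n : int
        Number of draws, ``n >= 1``.
    seed : int, numpy Generator, or None
        Source of randomness; a fixed integer gives reproducible draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = rng.beta(params.alpha, params.beta, size=n)
    return rng.binomial(params.m, q)


def gamma_link(p, kappa):
    """Household-level probability: inverse-logit of ``logit(p) + kappa``.

    Equals ``p`` exactly at ``kappa = 0`` and is strictly increasing in
    ``kappa``, always inside (0, 1).  This is the link through which the
    household random effects shift the group-level daily probability.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
        raise ValueError("p must be strictly inside (0, 1)")
    kappa_arr = np.asarray(kappa, dtype=float)
    if not np.all(np.isfinite(kappa_arr)):
        raise ValueError("kappa must be finite")
    out = expit(logit(p_arr) + kappa_arr)
    # expit underflows to exactly 0/1 for |x| > ~37; keep the open interval
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)
    return out if out.shape else float(out)
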