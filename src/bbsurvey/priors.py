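"""Prior families for the hierarchical beta-binomial model.

Two prior regimes are supported:

* diffuse baseline priors: ``p_j ~ Beta(1, 1)``, ``theta_j ~ Gamma(5, 1)``,
  ``sigma_j ~ Half-Cauchy(0, 2)``, ``Omega ~ LKJ(2)``;
* weighted informative priors for a follow-up round, built from a baseline
  fit (Beta/Gamma forms with weights ``a`` and ``alpha_w``; per-entry
  truncated-normal priors on the correlations) — see :mod:`bbsurvey.updating`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BetaPrior",
    "GammaPrior",
    "HalfCauchyPrior",
    "LKJPrior",
    "TruncNormCorrPrior",
    "PriorSpec",
    "default_diffuse_priors",
]


@dataclass(frozen=True)
class BetaPrior:
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes must be positive")

    def logpdf(self, p: float) -> float:
        return stats.beta.logpdf(p, self.a, self.b)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class GammaPrior:
    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("Gamma shape and rate must be positive")

    def logpdf(self, x: float) -> float:
        return stats.gamma.logpdf(x, self.shape, scale=1.0 / self.rate)

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2


@dataclass(frozen=True)
class HalfCauchyPrior:
    scale: float = 2.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("Half-Cauchy scale must be positive")

    def logpdf(self, x: float) -> float:
        return stats.halfcauchy.logpdf(x, scale=self.scale)


@dataclass(frozen=True)
class LKJPrior:
    """LKJ density on correlation matrices, proportional to det(Omega)^(eta-1)."""

    eta: float = 2.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("LKJ concentration must be positive")


@dataclass(frozen=True)
class TruncNormCorrPrior:
    """Independent truncated-normal priors on the entries of Omega.

    Each off-diagonal correlation rho_jk gets a Normal(means[j, k], sd)
    density truncated to (-1, 1).  Used when carrying baseline correlation
    estimates into a follow-up fit.
    """

    means: np.ndarray
    sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if np.any(np.abs(self.means) > 1):
            raise ValueError("correlation prior means must lie in [-1, 1]")


@dataclass
class PriorSpec:
    """Per-parameter prior families for one region model (J food groups)."""

    p: list[BetaPrior]
    theta: list[GammaPrior]
    sigma: list[HalfCauchyPrior]
    Omega: LKJPrior | TruncNormCorrPrior

    def __post_init__(self):
        J = len(self.p)
        if not (len(self.theta) == len(self.sigma) == J):
            raise ValueError("p, theta, sigma prior lists must have equal length")
        if isinstance(self.Omega, TruncNormCorrPrior) and self.Omega.means.shape != (J, J):
            raise ValueError("correlation prior means must be J x J")

    @property
    def J(self) -> int:
        return len(self.p)

    def log_prior_marginals(self, p, theta, sigma) -> float:
        """Sum of the per-group log prior densities (Omega handled separately)."""
        out = 0.0
        for j in range(self.J):
            out += self.p[j].logpdf(p[j])
            out += self.theta[j].logpdf(theta[j])
            out += self.sigma[j].logpdf(sigma[j])
        return float(out)

    def log_prior_omega(self, Omega: np.ndarray) -> float:
        """Log prior density of a correlation matrix, up to a constant."""
        if isinstance(self.Omega, LKJPrior):
            sign, logdet = np.linalg.slogdet(Omega)
            if sign <= 0:
                return -np.inf
            return (self.Omega.eta - 1.0) * logdet
        tri = np.triu_indices_from(Omega, k=1)
        rho = Omega[tri]
        if np.any(np.abs(rho) >= 1):
            return -np.inf
        mu = self.Omega.means[tri]
        return float(np.sum(-0.5 * ((rho - mu) / self.Omega.sd) ** 2))


def default_diffuse_priors(J: int) -> PriorSpec:
    """Diffuse baseline priors for a J-group model.

    ``Beta(1, 1)`` (uniform) on each daily probability, ``Gamma(5, 1)``
    (right-skewed, mean 5, 99% of mass below 11.6) on each dispersion,
    ``Half-Cauchy(0, 2)`` on each random-effect standard deviation, and
    ``LKJ(2)`` on the correlation matrix.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    return PriorSpec(
        p=[BetaPrior(1.0, 1.0) for _ in range(J)],
        theta=[GammaPrior(5.0, 1.0) for _ in range(J)],
        sigma=[HalfCauchyPrior(2.0) for _ in range(J)],
        Omega=LKJPrior(2.0),
    )
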