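"""The joint hierarchical model and the user-facing Model class.

Observation model for household i and food group j (m = 7 days):

    Y_ij | kappa_i ~ BetaBin(m, gamma_ij, theta_j)
    gamma_ij = inv-logit(logit(p_j) + kappa_ij)
    kappa_i ~ N(0, Sigma),  Sigma = D Omega D,  D = diag(sigma_1..sigma_J)

so p_j is the population daily consumption probability, theta_j the
within-household dispersion, sigma_j the across-household spread, and Omega
the correlation of consumption propensities across food groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .containers import ConsumptionMatrix, RegionParams
from .distributions import _logpmf_arrays, gamma_link
from .priors import PriorSpec, default_diffuse_priors

__all__ = ["HouseholdEffects", "joint_log_density", "ConsumptionModel"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class HouseholdEffects:
    """n x J matrix of household random effects kappa (logit-scale shifts)."""

    kappa: np.ndarray

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.ndim != 2:
            raise ValueError("kappa must be 2-D (households x groups)")
        if not np.all(np.isfinite(self.kappa)):
            raise ValueError("kappa entries must be finite")


def _mvn_logpdf_rows(kappa: np.ndarray, sigma: np.ndarray, Omega: np.ndarray) -> float:
    """Sum of N(0, D Omega D) log densities over the rows of kappa.

    Groups with sigma_j == 0 are degenerate: their kappa column must be 0 and
    they contribute no density term (point mass at zero).
    """
    active = sigma > 0
    if not np.all(np.abs(kappa[:, ~active]) < 1e-12):
        return -np.inf
    if not np.any(active):
        return 0.0
    sub = kappa[:, active]
    Sigma = np.outer(sigma[active], sigma[active]) * Omega[np.ix_(active, active)]
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    sol = solve_triangular(L, sub.T, lower=True)
    quad = float(np.sum(sol**2))
    n, d = sub.shape
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (quad + n * (logdet + d * _LOG_2PI))


def joint_log_density(
    data: ConsumptionMatrix,
    params: RegionParams,
    effects: HouseholdEffects,
    priors: PriorSpec | None = None,
) -> float:
    """Log prior + log random-effect density + conditional log likelihood.

    The three terms are: the prior density of (p, theta, sigma, Omega); the
    multivariate-normal density of the household effects; and the sum of
    beta-binomial log pmfs of the counts at the household-level probabilities
    ``gamma_ij = gamma_link(p_j, kappa_ij)``.
    """
    if priors is None:
        priors = default_diffuse_priors(params.J)
    if data.n_groups != params.J or effects.kappa.shape != data.counts.shape:
        raise ValueError("dimension mismatch between data, params, and effects")
    lp = priors.log_prior_marginals(params.p, params.theta, params.sigma)
    lp += priors.log_prior_omega(params.Omega)
    lp += _mvn_logpdf_rows(effects.kappa, params.sigma, params.Omega)
    if not np.isfinite(lp):
        return -np.inf
    gamma = gamma_link(params.p[None, :], effects.kappa)
    ll = _logpmf_arrays(data.counts, params.m, gamma, params.theta[None, :])
    return float(lp + ll.sum())


class ConsumptionModel:
    """Hierarchical multivariate beta-binomial model for one region's survey.

    Parameters
    ----------
    data : ConsumptionMatrix
        Weekly day counts, one row per household.
    priors : PriorSpec, optional
        Defaults to the diffuse baseline priors; pass the output of
        :func:`bbsurvey.updating.make_updated_priors` for a follow-up round.

    Examples
    --------
    >>> from bbsurvey import ConsumptionModel, scenario_library
    >>> from bbsurvey.synthdata import generate_survey
    >>> params = scenario_library()["ibb_2014"]
    >>> survey = generate_survey(params, n=480, seed=1)
    >>> results = ConsumptionModel(survey).fit(chains=4, iterations=2000,
    ...                                        warmup=500, seed=1)
    >>> print(results.summary())                       # doctest: +SKIP
    """

    def __init__(self, data: ConsumptionMatrix, priors: PriorSpec | None = None):
        self.data = data
        self.priors = priors if priors is not None else default_diffuse_priors(data.n_groups)
        if self.priors.J != data.n_groups:
            raise ValueError(
                f"priors are for {self.priors.J} groups but data has {data.n_groups}"
            )

    @classmethod
    def from_dataframe(cls, df, group_names=None, region=None, priors=None, m=7):
        data = ConsumptionMatrix.from_dataframe(df, group_names=group_names,
                                                region=region, m=m)
        return cls(data, priors=priors)

    def log_density(self, params: RegionParams, effects: HouseholdEffects) -> float:
        return joint_log_density(self.data, params, effects, self.priors)

    def fit(
        self,
        chains: int = 4,
        iterations: int = 4000,
        warmup: int = 1000,
        seed: int | None = None,
        fixed: dict | None = None,
        progress: bool = False,
    ):
        """Fit by adaptive Metropolis-within-Gibbs MCMC.

        Defaults mirror the reporting protocol (4 chains of 4000 steps, first
        1000 discarded as burn-in).  ``fixed`` may pin parameter blocks, e.g.
        ``{"theta": 1e6, "sigma": 0.0}`` for a pure-binomial reduction.

        Returns
        -------
        ConsumptionResults
        """
        from .inference import McmcConfig, fit

        config = McmcConfig(chains=chains, iterations=iterations, warmup=warmup,
                            seed=0 if seed is None else int(seed))
        return fit(self.data, self.priors, config, fixed=fixed, progress=progress)
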