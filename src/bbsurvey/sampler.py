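"""Adaptive Metropolis-within-Gibbs engine for the hierarchical model.

Sampling runs on unconstrained scales: logit(p_j), log(theta_j),
log(sigma_j), and atanh canonical partial correlations (CPCs) for Omega via
its Cholesky factor.  Under an LKJ(eta) prior the CPCs are independent with
(r+1)/2 ~ Beta(b, b), b = eta + (J - level - 1)/2, which gives a simple exact
prior in CPC space; truncated-normal priors on the correlations are applied
through the CPC -> Omega change of variables.

Each iteration sweeps:

1. a joint random-walk update of every household's random-effect row kappa_i
   (proposals pre-conditioned by the current Cholesky of Sigma, accepted
   household-by-household);
2. an exact translation move per group, (logit p_j, kappa[:, j]) ->
   (logit p_j + d, kappa[:, j] - d), which leaves the likelihood invariant
   and decorrelates the population probability from the mean random effect;
3. scalar random-walk updates of logit p_j, log theta_j, log sigma_j, and
   each CPC.

Proposal scales adapt by Robbins-Monro during warmup only, targeting
acceptance 0.25 for the row updates and 0.44 for scalars.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit

from .distributions import _logpmf_arrays
from .priors import LKJPrior, PriorSpec, TruncNormCorrPrior

__all__ = ["run_chain"]

_RMAX = 1.0 - 1e-9


def _cpc_to_chol(r_mat: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor of Omega from CPCs r_mat[k, i], k < i."""
    J = r_mat.shape[0]
    L = np.zeros((J, J))
    L[0, 0] = 1.0
    for i in range(1, J):
        rem = 1.0
        for k in range(i):
            L[i, k] = r_mat[k, i] * np.sqrt(rem)
            rem *= 1.0 - r_mat[k, i] ** 2
        L[i, i] = np.sqrt(rem)
    return L


def _tri_index(J: int):
    """(row, col) pairs for the free CPCs, ordered by tree level then column."""
    return [(k, i) for k in range(J - 1) for i in range(k + 1, J)]


class _State:
    """Mutable per-chain state with cached likelihood and Gaussian terms."""

    def __init__(self, Y, m, priors: PriorSpec, rng, fixed):
        self.Y = Y
        self.m = m
        self.n, self.J = Y.shape
        self.priors = priors
        fixed = fixed or {}

        def as_vec(v):
            return np.full(self.J, float(v)) if np.isscalar(v) else np.asarray(v, float)

        self.fix_p = "p" in fixed
        self.fix_theta = "theta" in fixed
        self.fix_sigma = "sigma" in fixed
        self.fix_omega = "Omega" in fixed

        phat = np.clip(Y.mean(0) / m, 0.02, 0.98)
        if self.fix_p:
            self.p = as_vec(fixed["p"])
        else:
            self.p = expit(np.log(phat / (1 - phat)) + 0.2 * rng.standard_normal(self.J))
        self.theta = as_vec(fixed["theta"]) if self.fix_theta else np.exp(
            np.log(5.0) + 0.3 * rng.standard_normal(self.J)
        )
        if self.fix_sigma:
            self.sigma = as_vec(fixed["sigma"])
            if np.any(self.sigma < 0):
                raise ValueError("fixed sigma must be non-negative")
        else:
            self.sigma = np.exp(0.3 * rng.standard_normal(self.J))
        # random effects are active unless sigma is pinned at exactly zero
        self.has_re = not (self.fix_sigma and np.all(self.sigma == 0.0))

        self.tri = _tri_index(self.J)
        self.K = len(self.tri)
        if self.fix_omega:
            Om = np.asarray(fixed["Omega"], float)
            Lom = cholesky(Om, lower=True)
            # back out CPCs so the cached construction stays consistent
            self.r = np.zeros((self.J, self.J))
            for k, i in self.tri:
                rem = np.prod([1 - self.r[kk, i] ** 2 for kk in range(k)]) if k else 1.0
                self.r[k, i] = Lom[i, k] / np.sqrt(rem) if rem > 0 else 0.0
        else:
            self.r = np.zeros((self.J, self.J))
        if self.has_re:
            # data-informed start: put each household's effect near the logit
            # residual of its own count, and sigma near the implied spread
            zp0 = np.log(phat / (1 - phat))
            resid = np.log((Y + 0.5) / (m + 0.5 - Y)) - zp0[None, :]
            self.kappa = 0.8 * resid
            if not self.fix_sigma:
                self.sigma = np.clip(self.kappa.std(0), 0.2, 4.0)
        else:
            self.kappa = np.zeros((self.n, self.J))
        self._rebuild_gauss()
        self._rebuild_lik()

    # -- cached quantities -------------------------------------------------
    def _rebuild_gauss(self):
        self.Lom = _cpc_to_chol(self.r)
        if self.has_re:
            sig = np.where(self.sigma > 0, self.sigma, 1e-300)
            self.Ls = sig[:, None] * self.Lom
            self.A = solve_triangular(self.Ls, self.kappa.T, lower=True)
            self.quad = np.sum(self.A**2, axis=0)
            self.logdet = 2.0 * float(np.sum(np.log(np.diag(self.Ls))))
        else:
            self.Ls = None
            self.quad = np.zeros(self.n)
            self.logdet = 0.0

    def _rebuild_lik(self):
        zp = np.log(self.p / (1 - self.p))
        self.gamma = expit(zp[None, :] + self.kappa)
        self.L = _logpmf_arrays(self.Y, self.m, self.gamma, self.theta[None, :])

    def gauss_logpdf(self, quad_sum=None, logdet=None):
        if not self.has_re:
            return 0.0
        q = self.quad.sum() if quad_sum is None else quad_sum
        ld = self.logdet if logdet is None else logdet
        return -0.5 * (q + self.n * ld)

    # -- priors on transformed scales -------------------------------------
    def lp_p(self, j, zpj):
        pr = self.priors.p[j]
        pj = expit(zpj)
        return (pr.a - 1) * np.log(pj) + (pr.b - 1) * np.log1p(-pj) + np.log(pj) + np.log1p(-pj)

    def lp_theta(self, j, ztj):
        pr = self.priors.theta[j]
        th = np.exp(ztj)
        return (pr.shape - 1) * ztj - pr.rate * th + ztj

    def lp_sigma(self, j, zsj):
        pr = self.priors.sigma[j]
        s = np.exp(zsj)
        return -np.log1p((s / pr.scale) ** 2) + zsj

    def lp_cpcs(self, r_mat):
        """Log prior of the CPC set, including all Jacobian terms."""
        out = 0.0
        if isinstance(self.priors.Omega, LKJPrior):
            eta = self.priors.Omega.eta
            for k, i in self.tri:
                b = eta + (self.J - k - 2) / 2.0
                out += b * np.log1p(-r_mat[k, i] ** 2)
            return out
        # truncated-normal on the implied correlations + CPC->Omega Jacobian
        Lom = _cpc_to_chol(r_mat)
        Om = Lom @ Lom.T
        mu = self.priors.Omega.means
        sd = self.priors.Omega.sd
        for k, i in self.tri:
            out += (self.J - k - 2) / 2.0 * np.log1p(-r_mat[k, i] ** 2)
            out += np.log1p(-r_mat[k, i] ** 2)  # atanh Jacobian
            out += -0.5 * ((Om[k, i] - mu[k, i]) / sd) ** 2
        return out


def run_chain(Y, m, priors, iterations, warmup, rng, fixed=None, thin=1):
    """Run one MCMC chain; returns a dict of retained draws."""
    st = _State(Y, m, priors, rng, fixed)
    n, J = st.n, st.J

    s_kappa = np.full(n, 0.5)
    s_p = np.full(J, 0.3)
    s_t = np.full(J, 0.4)
    s_s = np.full(J, 0.3)
    s_r = np.full(st.K, 0.3)
    s_shift = np.full(J, 0.2)
    s_s2 = np.full(J, 0.3)
    s_r2 = np.full(st.K, 0.3)
    s_ts = np.full(J, 0.3)

    kept = iterations - warmup
    out = {
        "p": np.empty((kept, J)),
        "theta": np.empty((kept, J)),
        "sigma": np.empty((kept, J)),
        "Omega": np.empty((kept, J, J)),
        "logpost": np.empty(kept),
    }

    zp = np.log(st.p / (1 - st.p))
    zt = np.log(st.theta)
    zs = np.log(np.where(st.sigma > 0, st.sigma, 1.0))

    def adapt(scale, acc, target, t):
        return float(np.clip(scale * np.exp((acc - target) / (t + 1) ** 0.6 * 3.0),
                             1e-3, 20.0))

    for t in range(iterations):
        adapting = t < warmup

        # 1. household random-effect rows
        if st.has_re:
            eps = rng.standard_normal((n, J))
            prop = st.kappa + s_kappa[:, None] * (eps @ st.Ls.T)
            gamma_p = expit(zp[None, :] + prop)
            np.clip(gamma_p, 1e-300, 1 - 1e-16, out=gamma_p)
            L_p = _logpmf_arrays(st.Y, m, gamma_p, st.theta[None, :])
            A_p = solve_triangular(st.Ls, prop.T, lower=True)
            quad_p = np.sum(A_p**2, axis=0)
            logr = (L_p - st.L).sum(1) - 0.5 * (quad_p - st.quad)
            acc_rows = np.log(rng.random(n)) < logr
            st.kappa[acc_rows] = prop[acc_rows]
            st.L[acc_rows] = L_p[acc_rows]
            st.gamma[acc_rows] = gamma_p[acc_rows]
            st.A[:, acc_rows] = A_p[:, acc_rows]
            st.quad[acc_rows] = quad_p[acc_rows]
            if adapting:
                # per-household Robbins-Monro on the acceptance indicator
                step = 3.0 / (t + 1) ** 0.6
                s_kappa = np.clip(
                    s_kappa * np.exp(step * (acc_rows - 0.25)), 1e-3, 20.0)

        # 2. exact translation moves (likelihood-invariant)
        if st.has_re and not st.fix_p:
            eye = np.eye(J)
            for j in range(J):
                d = s_shift[j] * rng.standard_normal()
                w = solve_triangular(st.Ls, eye[:, j], lower=True)
                wa = w @ st.A
                dquad = -2.0 * d * wa + d * d * float(w @ w)
                logr = st.lp_p(j, zp[j] + d) - st.lp_p(j, zp[j]) - 0.5 * dquad.sum()
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zp[j] += d
                    st.p[j] = expit(zp[j])
                    st.kappa[:, j] -= d
                    st.A -= d * w[:, None]
                    st.quad += dquad
                if adapting:
                    s_shift[j] = adapt(s_shift[j], 1.0 if accepted else 0.0, 0.44, t)

        # 3. scalar updates
        if not st.fix_p:
            for j in range(J):
                z_new = zp[j] + s_p[j] * rng.standard_normal()
                p_new = expit(z_new)
                gcol = expit(z_new + st.kappa[:, j])
                gcol = np.clip(gcol, 1e-300, 1 - 1e-16)
                Lcol = _logpmf_arrays(st.Y[:, j], m, gcol, st.theta[j])
                logr = (Lcol - st.L[:, j]).sum() + st.lp_p(j, z_new) - st.lp_p(j, zp[j])
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zp[j] = z_new
                    st.p[j] = p_new
                    st.L[:, j] = Lcol
                    st.gamma[:, j] = gcol
                if adapting:
                    s_p[j] = adapt(s_p[j], 1.0 if accepted else 0.0, 0.44, t)

        if not st.fix_theta:
            for j in range(J):
                z_new = zt[j] + s_t[j] * rng.standard_normal()
                th_new = np.exp(z_new)
                Lcol = _logpmf_arrays(st.Y[:, j], m, st.gamma[:, j], th_new)
                logr = (Lcol - st.L[:, j]).sum() + st.lp_theta(j, z_new) - st.lp_theta(j, zt[j])
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zt[j] = z_new
                    st.theta[j] = th_new
                    st.L[:, j] = Lcol
                if adapting:
                    s_t[j] = adapt(s_t[j], 1.0 if accepted else 0.0, 0.44, t)

        if st.has_re and not st.fix_sigma:
            for j in range(J):
                z_new = zs[j] + s_s[j] * rng.standard_normal()
                sig_new = st.sigma.copy()
                sig_new[j] = np.exp(z_new)
                Ls_new = sig_new[:, None] * st.Lom
                A_new = solve_triangular(Ls_new, st.kappa.T, lower=True)
                quad_new = np.sum(A_new**2, axis=0)
                logdet_new = 2.0 * float(np.sum(np.log(np.diag(Ls_new))))
                logr = (
                    st.gauss_logpdf(quad_new.sum(), logdet_new)
                    - st.gauss_logpdf()
                    + st.lp_sigma(j, z_new)
                    - st.lp_sigma(j, zs[j])
                )
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zs[j] = z_new
                    st.sigma = sig_new
                    st.Ls = Ls_new
                    st.A = A_new
                    st.quad = quad_new
                    st.logdet = logdet_new
                if adapting:
                    s_s[j] = adapt(s_s[j], 1.0 if accepted else 0.0, 0.44, t)

        if st.has_re and not st.fix_omega:
            lp_r_cur = st.lp_cpcs(st.r)
            for idx, (k, i) in enumerate(st.tri):
                z_cur = np.arctanh(np.clip(st.r[k, i], -_RMAX, _RMAX))
                z_new = z_cur + s_r[idx] * rng.standard_normal()
                r_new = st.r.copy()
                r_new[k, i] = float(np.clip(np.tanh(z_new), -_RMAX, _RMAX))
                Lom_new = _cpc_to_chol(r_new)
                sig = np.where(st.sigma > 0, st.sigma, 1e-300)
                Ls_new = sig[:, None] * Lom_new
                A_new = solve_triangular(Ls_new, st.kappa.T, lower=True)
                quad_new = np.sum(A_new**2, axis=0)
                logdet_new = 2.0 * float(np.sum(np.log(np.diag(Ls_new))))
                lp_r_new = st.lp_cpcs(r_new)
                logr = (
                    st.gauss_logpdf(quad_new.sum(), logdet_new)
                    - st.gauss_logpdf()
                    + lp_r_new
                    - lp_r_cur
                )
                accepted = np.log(rng.random()) < logr
                if accepted:
                    st.r = r_new
                    st.Lom = Lom_new
                    st.Ls = Ls_new
                    st.A = A_new
                    st.quad = quad_new
                    st.logdet = logdet_new
                    lp_r_cur = lp_r_new
                if adapting:
                    s_r[idx] = adapt(s_r[idx], 1.0 if accepted else 0.0, 0.44, t)

        # 4. non-centered (interwoven) updates: hold the whitened effects
        # kappa_tilde = Ls^-1 kappa fixed, so sigma/Omega moves rescale kappa
        # and are informed by the likelihood; this breaks the slow critical
        # dynamics of the centered updates when sigma or theta is confounded.
        if st.has_re and not st.fix_sigma:
            for j in range(J):
                z_new = zs[j] + s_s2[j] * rng.standard_normal()
                sig_j_new = np.exp(z_new)
                ratio = sig_j_new / st.sigma[j]
                kcol = st.kappa[:, j] * ratio
                gcol = expit(zp[j] + kcol)
                gcol = np.clip(gcol, 1e-300, 1 - 1e-16)
                Lcol = _logpmf_arrays(st.Y[:, j], m, gcol, st.theta[j])
                logr = (Lcol - st.L[:, j]).sum() + st.lp_sigma(j, z_new) - st.lp_sigma(j, zs[j])
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zs[j] = z_new
                    st.sigma = st.sigma.copy()
                    st.sigma[j] = sig_j_new
                    st.kappa[:, j] = kcol
                    st.gamma[:, j] = gcol
                    st.L[:, j] = Lcol
                    st.Ls = st.Ls.copy()
                    st.Ls[j, :] *= ratio
                    st.logdet += 2.0 * np.log(ratio)
                if adapting:
                    s_s2[j] = adapt(s_s2[j], 1.0 if accepted else 0.0, 0.44, t)

        # joint dispersion move along the theta/sigma trade-off valley:
        # raising theta_j (less within-household dispersion) while raising
        # sigma_j (more across-household spread) leaves the marginal count
        # variance nearly unchanged, so the two must move together
        if st.has_re and not (st.fix_sigma or st.fix_theta):
            for j in range(J):
                u = s_ts[j] * rng.standard_normal()
                g = np.exp(u)
                kcol = st.kappa[:, j] * g
                gcol = expit(zp[j] + kcol)
                gcol = np.clip(gcol, 1e-300, 1 - 1e-16)
                Lcol = _logpmf_arrays(st.Y[:, j], m, gcol, st.theta[j] * g)
                logr = ((Lcol - st.L[:, j]).sum()
                        + st.lp_theta(j, zt[j] + u) - st.lp_theta(j, zt[j])
                        + st.lp_sigma(j, zs[j] + u) - st.lp_sigma(j, zs[j]))
                accepted = np.log(rng.random()) < logr
                if accepted:
                    zt[j] += u
                    zs[j] += u
                    st.theta = st.theta.copy()
                    st.theta[j] *= g
                    st.sigma = st.sigma.copy()
                    st.sigma[j] *= g
                    st.kappa[:, j] = kcol
                    st.gamma[:, j] = gcol
                    st.L[:, j] = Lcol
                    st.Ls = st.Ls.copy()
                    st.Ls[j, :] *= g
                    st.logdet += 2.0 * u
                if adapting:
                    s_ts[j] = adapt(s_ts[j], 1.0 if accepted else 0.0, 0.44, t)

        if st.has_re and not st.fix_omega:
            lp_r_cur = st.lp_cpcs(st.r)
            for idx, (k, i) in enumerate(st.tri):
                z_cur = np.arctanh(np.clip(st.r[k, i], -_RMAX, _RMAX))
                z_new = z_cur + s_r2[idx] * rng.standard_normal()
                r_new = st.r.copy()
                r_new[k, i] = float(np.clip(np.tanh(z_new), -_RMAX, _RMAX))
                Lom_new = _cpc_to_chol(r_new)
                # only row i of the Cholesky factor changes
                ls_row_new = st.sigma[i] * Lom_new[i, :]
                kcol = ls_row_new @ st.A
                gcol = expit(zp[i] + kcol)
                gcol = np.clip(gcol, 1e-300, 1 - 1e-16)
                Lcol = _logpmf_arrays(st.Y[:, i], m, gcol, st.theta[i])
                lp_r_new = st.lp_cpcs(r_new)
                logr = (Lcol - st.L[:, i]).sum() + lp_r_new - lp_r_cur
                accepted = np.log(rng.random()) < logr
                if accepted:
                    st.r = r_new
                    st.Lom = Lom_new
                    st.Ls = st.Ls.copy()
                    st.Ls[i, :] = ls_row_new
                    st.kappa[:, i] = kcol
                    st.gamma[:, i] = gcol
                    st.L[:, i] = Lcol
                    st.logdet = 2.0 * float(np.sum(np.log(np.diag(st.Ls))))
                    lp_r_cur = lp_r_new
                if adapting:
                    s_r2[idx] = adapt(s_r2[idx], 1.0 if accepted else 0.0, 0.44, t)

        if t >= warmup:
            s = t - warmup
            out["p"][s] = st.p
            out["theta"][s] = st.theta
            out["sigma"][s] = st.sigma
            out["Omega"][s] = st.Lom @ st.Lom.T
            lp = st.L.sum() + st.gauss_logpdf()
            for j in range(J):
                lp += st.lp_p(j, zp[j]) + st.lp_theta(j, zt[j])
                if st.has_re:
                    lp += st.lp_sigma(j, zs[j])
            out["logpost"][s] = lp

    return out
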