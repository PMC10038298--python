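import numpy as np
import pytest
from scipy import stats
from scipy.special import betaln, gammaln

from bbsurvey.containers import ConsumptionMatrix
from bbsurvey.model import ConsumptionModel
from bbsurvey.priors import BetaPrior, GammaPrior, HalfCauchyPrior, TruncNormCorrPrior
from bbsurvey.updating import (
    BaselineSummary,
    UpdateWeights,
    baseline_beta_posterior,
    make_updated_priors,
    normal_approx_posterior,
    planning_halfwidth_p,
    updated_beta_moments,
)


class TestBaselineBetaPosterior:
    def test_symmetric_case(self):
        res = baseline_beta_posterior(100, 0.5)
        assert res["mean"] == pytest.approx(351 / 702)
        assert res["a"] == pytest.approx(351)
        assert res["b"] == pytest.approx(351)

    def test_sd_bound_at_n0_100(self):
        worst = max(
            baseline_beta_posterior(100, ph)["sd"] for ph in np.linspace(0, 1, 201)
        )
        assert worst <= 0.02

    def test_monte_carlo_oracle(self):
        res = baseline_beta_posterior(480, 0.4)
        rng = np.random.default_rng(17)
        draws = rng.beta(res["a"], res["b"], 10**6)
        assert res["mean"] == pytest.approx(draws.mean(), abs=5 * res["sd"] / 1000)
        assert res["sd"] == pytest.approx(draws.std(), rel=0.01)


class TestMakeUpdatedPriors:
    def _base(self, phat=None):
        J = 3
        return BaselineSummary(
            n0=480,
            group_names=["a", "b", "c"],
            phat0=np.array([0.4, 0.2, 0.7]) if phat is None else phat,
            theta_hat0=np.array([5.0, 2.0, 8.0]),
            sigma_hat0=np.ones(J),
            rho_hat0=np.eye(J),
        )

    def test_beta_and_gamma_forms(self):
        priors = make_updated_priors(self._base(), UpdateWeights(a=50, alpha_w=5))
        assert isinstance(priors.p[0], BetaPrior)
        assert priors.p[0].a == pytest.approx(20.0)
        assert priors.p[0].b == pytest.approx(30.0)
        assert priors.p[0].mean == pytest.approx(0.4)
        assert isinstance(priors.theta[0], GammaPrior)
        assert priors.theta[0].shape == pytest.approx(25.0)
        assert priors.theta[0].rate == pytest.approx(5.0)
        assert priors.theta[0].mean == pytest.approx(5.0)
        assert priors.theta[0].variance == pytest.approx(1.0)
        assert isinstance(priors.sigma[0], HalfCauchyPrior)
        assert priors.sigma[0].scale == 2.0
        assert isinstance(priors.Omega, TruncNormCorrPrior)
        assert priors.Omega.sd == 1.0

    def test_degenerate_phat_clamped(self):
        base = self._base(phat=np.array([0.0, 1.0, 0.5]))
        priors = make_updated_priors(base, UpdateWeights(a=50, alpha_w=5))
        eps = 1 / (7 * 480 + 2)
        assert priors.p[0].mean == pytest.approx(eps)
        assert priors.p[1].mean == pytest.approx(1 - eps)


class TestUpdatedBetaMoments:
    def test_printed_formula(self):
        mean, _ = updated_beta_moments(0.2, 50, 100, 0.3)
        assert mean == pytest.approx((10 + 210) / 750)

    def test_fixed_point(self):
        mean, _ = updated_beta_moments(0.37, 50, 200, 0.37)
        assert mean == pytest.approx(0.37)

    @pytest.mark.parametrize("p0,pd", [(0.2, 0.6), (0.8, 0.3)])
    def test_mean_between_and_monotone_in_a(self, p0, pd):
        means = [updated_beta_moments(p0, a, 150, pd)[0] for a in (5, 50, 500, 5000)]
        for m in means:
            assert min(p0, pd) <= m <= max(p0, pd)
        dists = [abs(m - p0) for m in means]
        assert dists == sorted(dists, reverse=True)


class TestNormalApprox:
    def test_mle_limit_with_negligible_prior(self):
        rng = np.random.default_rng(23)
        counts = rng.binomial(7, 0.45, size=400)
        res = normal_approx_posterior(
            0.2, 5.0, UpdateWeights(a=1e-6, alpha_w=1e-6), counts=counts
        )
        assert res["mode"][0] == pytest.approx(counts.mean() / 7, abs=0.01)

    def test_grid_oracle(self):
        # dense quadrature over (p, theta) as the independent reference
        w_scenario, nd = (0.4, 5.0), 360
        weights = UpdateWeights(a=50, alpha_w=5)
        res = normal_approx_posterior(0.4, 5.0, weights, scenario=w_scenario, nd=nd)

        ys = np.arange(8.0)
        logC = gammaln(8) - gammaln(ys + 1) - gammaln(8 - ys)
        a_d, b_d = 0.4 * 5.0, 0.6 * 5.0
        w = nd * np.exp(logC + betaln(ys + a_d, 7 - ys + b_d) - betaln(a_d, b_d))
        pg = np.linspace(0.25, 0.55, 300)
        tg = np.linspace(1.0, 15.0, 300)
        P, T = np.meshgrid(pg, tg, indexing="ij")
        lp = np.zeros_like(P)
        for k in range(8):
            A, B = P * T, (1 - P) * T
            lp += w[k] * (logC[k] + betaln(k + A, 7 - k + B) - betaln(A, B))
        lp += (20 - 1) * np.log(P) + (30 - 1) * np.log(1 - P)
        lp += (25 - 1) * np.log(T) - 5 * T
        post = np.exp(lp - lp.max())
        post /= post.sum()
        marg_p = post.sum(1)
        mu_p = float((pg * marg_p).sum())
        sd_p = float(np.sqrt((pg**2 * marg_p).sum() - mu_p**2))

        assert res["mode"][0] == pytest.approx(mu_p, abs=0.005)
        assert res["halfwidth_p"] == pytest.approx(1.96 * sd_p, rel=0.05)

    def test_halfwidth_shrinks_with_nd(self):
        weights = UpdateWeights(a=50, alpha_w=5)
        widths = [
            normal_approx_posterior(0.4, 5.0, weights, scenario=(0.4, 5.0), nd=nd)[
                "halfwidth_p"
            ]
            for nd in (250, 500, 1000)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_requires_data(self):
        with pytest.raises(ValueError):
            normal_approx_posterior(0.4, 5.0, UpdateWeights())


def test_planning_halfwidth_p_closed_form():
    # the bound is attained at p0 = pd = 0.5 and equals the maximal Beta sd
    got = planning_halfwidth_p(a=50, nd=360, grid_points=51)
    expected = 1.96 * np.sqrt(0.25 / (50 + 7 * 360 + 1))
    assert got == pytest.approx(expected, rel=1e-6)


def test_prior_weight_bias_monotonicity():
    """Posterior mean of p moves from the data toward the baseline as a grows."""
    rng = np.random.default_rng(31)
    counts = rng.binomial(7, 0.45, size=200)  # follow-up data near 0.45
    data = ConsumptionMatrix(counts=counts[:, None], group_names=["g"])
    phat0 = 0.25  # baseline far below the new data
    base = BaselineSummary(
        n0=480, group_names=["g"], phat0=np.array([phat0]),
        theta_hat0=np.array([5.0]), sigma_hat0=np.array([1.0]),
        rho_hat0=np.eye(1),
    )
    means = []
    for a in (5, 50, 500):
        priors = make_updated_priors(base, UpdateWeights(a=a, alpha_w=5))
        res = ConsumptionModel(data, priors=priors).fit(
            chains=2, iterations=1000, warmup=400, seed=8,
            fixed={"sigma": 0.0},
        )
        means.append(res.draws.stacked("p")[:, 0].mean())
    dists = [abs(m - phat0) for m in means]
    assert dists[0] > dists[1] > dists[2]


def test_baseline_summary_json_roundtrip(tmp_path):
    base = BaselineSummary(
        n0=100, group_names=["a", "b"], phat0=[0.2, 0.8],
        theta_hat0=[3.0, 4.0], sigma_hat0=[1.0, 2.0], rho_hat0=np.eye(2),
    )
    path = tmp_path / "base.json"
    base.to_json(path, region="toy")
    back = BaselineSummary.from_json(path)
    assert back.n0 == 100
    np.testing.assert_allclose(back.phat0, base.phat0)
    np.testing.assert_allclose(back.rho_hat0, base.rho_hat0)
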