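"""Bayesian grid posterior vs numerical-quadrature oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, interpolate, stats

import metapool as mp
from metapool.exceptions import EmptyEvidenceError, TruncationError

Z95 = 1.959963984540054


def make_effects(ys, vs):
    return [mp.EffectEstimate(f"s{i}", y, v) for i, (y, v) in enumerate(zip(ys, vs))]


def quad_marginal_mu_quantiles(effects, prior, qs, tau_upper=20.0, n_mu=1201):
    """Independent oracle: 2-D numerical integration over (mu, tau).

    For each point of a fine mu grid, integrate the joint density over tau
    with adaptive quadrature; quantiles come from the interpolated CDF.
    """
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])

    def joint(tau, mu):
        s2 = v + tau**2
        lik = np.prod(stats.norm.pdf(y, mu, np.sqrt(s2)))
        pr_tau = math.sqrt(float((tau**2 / s2**2).sum()))  # Jeffreys
        pr_mu = stats.norm.pdf(mu, prior.m0, math.sqrt(prior.s0_sq))
        return pr_tau * lik * pr_mu

    lo = min(y.min(), prior.m0) - 6 * math.sqrt(v.max() + prior.s0_sq)
    hi = max(y.max(), prior.m0) + 6 * math.sqrt(v.max() + prior.s0_sq)
    mu_grid = np.linspace(lo, hi, n_mu)
    dens = np.array(
        [integrate.quad(joint, 0, tau_upper, args=(m,), limit=200)[0] for m in mu_grid]
    )
    cdf = integrate.cumulative_trapezoid(dens, mu_grid, initial=0.0)
    cdf /= cdf[-1]
    inv = interpolate.interp1d(cdf, mu_grid)
    return [float(inv(q)) for q in qs]


class TestMarginalLikelihood:
    def test_k1_tau0_is_convolution_of_two_normals(self):
        eff = make_effects([0.4], [0.04])
        prior = mp.NormalPrior(0.1, 0.5)
        got = mp.marginal_likelihood_given_tau(eff, prior, 0.0)
        want = stats.norm.logpdf(0.4, 0.1, math.sqrt(0.04 + 0.5))
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.0, 0.15, 0.6])
    def test_agrees_with_1d_quadrature(self, tau, rng):
        eff = make_effects(rng.normal(0.3, 0.4, 5), rng.uniform(0.02, 0.3, 5))
        prior = mp.vague_prior()
        y = np.array([e.y for e in eff])
        v = np.array([e.v for e in eff])

        def integrand(mu):
            return np.prod(stats.norm.pdf(y, mu, np.sqrt(v + tau**2))) * stats.norm.pdf(
                mu, prior.m0, math.sqrt(prior.s0_sq)
            )

        want, _ = integrate.quad(integrand, -20, 20, limit=200)
        got = mp.marginal_likelihood_given_tau(eff, prior, tau)
        assert got == pytest.approx(math.log(want), abs=1e-8)

    def test_invariant_to_study_order(self, rng):
        eff = make_effects(rng.normal(0, 0.5, 6), rng.uniform(0.05, 0.4, 6))
        prior = mp.vague_prior()
        a = mp.marginal_likelihood_given_tau(eff, prior, 0.3)
        b = mp.marginal_likelihood_given_tau(eff[::-1], prior, 0.3)
        assert a == pytest.approx(b, rel=1e-14)


class TestConjugateClosedForm:
    def test_tau_forced_to_zero_matches_closed_form(self):
        # one study y=0.4, v=0.04, prior N(0, 0.5):
        # posterior mean (0.4/0.04)/(1/0.04 + 1/0.5) = 10/27, variance 1/27
        eff = make_effects([0.4], [0.04])
        post = mp.posterior(eff, mp.NormalPrior(0.0, 0.5), het=mp.HeterogeneityPrior.fixed(0.0))
        mean, var = 10.0 / 27.0, 1.0 / 27.0
        assert post.mu_median == pytest.approx(mean, abs=1e-8)
        assert post.mu_mean == pytest.approx(mean, abs=1e-12)
        z = stats.norm.ppf(0.975)
        assert post.cri_lower_log == pytest.approx(mean - z * math.sqrt(var), abs=1e-8)
        assert post.cri_upper_log == pytest.approx(mean + z * math.sqrt(var), abs=1e-8)

    def test_flat_prior_limit_recovers_fixed_effect(self, two_studies):
        post = mp.posterior(
            two_studies, mp.NormalPrior(0.0, 1e8), het=mp.HeterogeneityPrior.fixed(0.0)
        )
        fe = mp.fixed_effect_pool(two_studies)
        assert post.mu_mean == pytest.approx(fe.mu_hat, abs=1e-6)

    def test_dogmatic_prior_pins_posterior_at_prior_mean(self, two_studies):
        post = mp.posterior(two_studies, mp.NormalPrior(0.35, 1e-8))
        assert post.mu_median == pytest.approx(0.35, abs=1e-3)

    def test_posterior_mean_lies_between_prior_and_fixed_effect(self, two_studies):
        fe = mp.fixed_effect_pool(two_studies).mu_hat
        m0 = 0.0
        prev_dist = None
        for s0 in (0.01, 0.1, 1.0, 10.0):
            post = mp.posterior(
                two_studies, mp.NormalPrior(m0, s0), het=mp.HeterogeneityPrior.fixed(0.0)
            )
            assert min(m0, fe) - 1e-12 <= post.mu_mean <= max(m0, fe) + 1e-12
            dist = abs(post.mu_mean - fe)
            if prev_dist is not None:  # widening the prior moves toward mu_FE
                assert dist < prev_dist
            prev_dist = dist


class TestGridPosterior:
    def test_matches_2d_quadrature_oracle(self, rng):
        eff = make_effects(rng.normal(0.4, 0.45, 5), rng.uniform(0.03, 0.25, 5))
        prior = mp.vague_prior()
        post = mp.posterior(eff, prior)
        med, lo, hi = quad_marginal_mu_quantiles(eff, prior, [0.5, 0.025, 0.975])
        assert post.mu_median == pytest.approx(med, abs=1e-3)
        assert post.cri_lower_log == pytest.approx(lo, abs=1e-3)
        assert post.cri_upper_log == pytest.approx(hi, abs=1e-3)

    def test_tau_density_normalized_and_quantiles_ordered(self, fixture_base):
        post = mp.posterior(fixture_base.effects(), mp.vague_prior())
        taus = np.array([t for t, _ in post.tau_grid])
        dens = np.array([d for _, d in post.tau_grid])
        assert np.trapezoid(dens, taus) == pytest.approx(1.0, abs=1e-6)
        assert post.cri_lower_log < post.mu_median < post.cri_upper_log

    def test_doubling_uncertainty_widens_interval(self, two_studies):
        prior = mp.vague_prior()
        post1 = mp.posterior(two_studies, prior)
        doubled = [mp.EffectEstimate(e.study_id, e.y, 2 * e.v) for e in two_studies]
        post2 = mp.posterior(doubled, mp.NormalPrior(prior.m0, 2 * prior.s0_sq))
        w1 = post1.cri_upper_log - post1.cri_lower_log
        w2 = post2.cri_upper_log - post2.cri_lower_log
        assert w2 > w1

    def test_truncated_grid_raises(self, rng):
        # strongly heterogeneous data with tau_max far too small
        eff = make_effects([-2.0, -0.5, 1.0, 2.5], [0.01] * 4)
        with pytest.raises(TruncationError):
            mp.posterior(eff, mp.vague_prior(), het=mp.HeterogeneityPrior.jeffreys(tau_max=0.01))

    def test_empty_effects_rejected(self):
        with pytest.raises(EmptyEvidenceError):
            mp.posterior([], mp.vague_prior())

    def test_half_normal_and_uniform_priors_run(self, two_studies):
        for het in (
            mp.HeterogeneityPrior.half_normal(0.5),
            mp.HeterogeneityPrior.uniform(2.0),
        ):
            post = mp.posterior(two_studies, mp.vague_prior(), het=het)
            assert post.cri_lower_log < post.mu_median < post.cri_upper_log
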