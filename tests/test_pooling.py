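"""Frequentist engine vs exact rational arithmetic and statsmodels."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metapool as mp
from metapool.exceptions import EmptyEvidenceError, InsufficientStudiesError


def oracle_pool(ys, vs):
    """Brute-force oracle: direct formula evaluation in exact rational arithmetic.

    Binary floats are exact rationals, so Fraction reproduces the defining
    formulas with zero rounding error.
    """
    y = [Fraction(x) for x in ys]
    v = [Fraction(x) for x in vs]
    w = [1 / vi for vi in v]
    s1 = sum(w)
    mu_fe = sum(wi * yi for wi, yi in zip(w, y)) / s1
    var_fe = 1 / s1
    Q = sum(wi * (yi - mu_fe) ** 2 for wi, yi in zip(w, y))
    k = len(y)
    out = {"mu_fe": mu_fe, "var_fe": var_fe, "Q": Q}
    if k >= 2:
        s2 = sum(wi**2 for wi in w)
        tau2 = max(Fraction(0), (Q - (k - 1)) / (s1 - s2 / s1))
        ws = [1 / (vi + tau2) for vi in v]
        sws = sum(ws)
        out["tau2"] = tau2
        out["mu_re"] = sum(wi * yi for wi, yi in zip(ws, y)) / sws
        out["var_re"] = 1 / sws
    return out


def random_instance(rng, k):
    y = rng.normal(0, 0.6, size=k)
    v = rng.uniform(0.005, 0.5, size=k)
    return [mp.EffectEstimate(f"s{i}", float(y[i]), float(v[i])) for i in range(k)]


class TestHandChecked:
    def test_two_study_toy(self, two_studies):
        fe = mp.fixed_effect_pool(two_studies)
        assert fe.mu_hat == pytest.approx(0.3, abs=1e-14)
        assert fe.var_mu == pytest.approx(0.02, abs=1e-14)
        assert mp.cochran_q(two_studies) == pytest.approx(2.0, abs=1e-12)
        assert mp.dl_tau2(two_studies) == pytest.approx(0.04, abs=1e-14)
        re = mp.random_effects_pool(two_studies)
        assert re.mu_hat == pytest.approx(0.3, abs=1e-14)
        assert re.var_mu == pytest.approx(0.04, abs=1e-14)
        assert re.weights == pytest.approx((0.5, 0.5))

    def test_single_study_identity(self):
        eff = [mp.EffectEstimate("a", 0.4, 0.04)]
        fe = mp.fixed_effect_pool(eff)
        assert fe.mu_hat == 0.4
        assert fe.var_mu == 0.04
        assert fe.ci_upper_log == pytest.approx(0.4 + 1.959964 * 0.2, rel=1e-5)
        assert fe.Q == 0.0 and fe.tau2 == 0.0

    def test_identical_studies_have_zero_q_and_tau2(self):
        eff = [mp.EffectEstimate(f"s{i}", 0.3, 0.1) for i in range(3)]
        assert mp.cochran_q(eff) == pytest.approx(0.0, abs=1e-14)
        assert mp.dl_tau2(eff) == 0.0
        # degenerate case: random-effects collapses to fixed-effect
        fe, re = mp.fixed_effect_pool(eff), mp.random_effects_pool(eff)
        assert re.mu_hat == pytest.approx(fe.mu_hat) and re.var_mu == pytest.approx(fe.var_mu)

    @pytest.mark.parametrize("Q, k, expected", [(2.0, 2, 0.5), (0.0, 5, 0.0), (4.0, 5, 0.0)])
    def test_i_squared(self, Q, k, expected):
        assert mp.i_squared(Q, k) == pytest.approx(expected)

    def test_sign_symmetry(self, two_studies):
        neg = [mp.EffectEstimate(e.study_id, -e.y, e.v) for e in two_studies]
        a, b = mp.random_effects_pool(two_studies), mp.random_effects_pool(neg)
        assert b.mu_hat == pytest.approx(-a.mu_hat, abs=1e-14)
        assert b.var_mu == pytest.approx(a.var_mu, abs=1e-14)

    def test_equal_variances_give_unweighted_mean(self, rng):
        y = rng.normal(0, 1, size=6)
        eff = [mp.EffectEstimate(f"s{i}", float(yi), 0.05) for i, yi in enumerate(y)]
        re = mp.random_effects_pool(eff)
        assert re.mu_hat == pytest.approx(float(np.mean(y)), abs=1e-12)

    def test_error_conditions(self):
        with pytest.raises(EmptyEvidenceError):
            mp.fixed_effect_pool([])
        one = [mp.EffectEstimate("a", 0.1, 0.1)]
        for op in (mp.dl_tau2, mp.random_effects_pool):
            with pytest.raises(InsufficientStudiesError):
                op(one)
        with pytest.raises(InsufficientStudiesError):
            mp.i_squared(1.0, 1)


class TestOracleAgreement:
    def test_exact_rational_oracle_small_batch(self, rng):
        for _ in range(50):
            eff = random_instance(rng, int(rng.integers(2, 12)))
            ora = oracle_pool([e.y for e in eff], [e.v for e in eff])
            fe = mp.fixed_effect_pool(eff)
            re = mp.random_effects_pool(eff)
            assert abs(fe.mu_hat - float(ora["mu_fe"])) < 1e-10
            assert abs(fe.Q - float(ora["Q"])) < 1e-10
            assert abs(re.tau2 - float(ora["tau2"])) < 1e-10
            assert abs(re.mu_hat - float(ora["mu_re"])) < 1e-10
            assert abs(re.var_mu - float(ora["var_re"])) < 1e-10

    def test_statsmodels_cross_check(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        for _ in range(10):
            eff = random_instance(rng, int(rng.integers(3, 15)))
            y = np.array([e.y for e in eff])
            v = np.array([e.v for e in eff])
            res = combine_effects(y, v, method_re="dl")
            fe = mp.fixed_effect_pool(eff)
            re = mp.random_effects_pool(eff)
            assert fe.mu_hat == pytest.approx(res.mean_effect_fe, rel=1e-10)
            assert fe.Q == pytest.approx(res.q, rel=1e-10)
            # statsmodels returns the untruncated moment estimate; standard
            # DerSimonian-Laird truncates tau^2 at zero
            assert re.tau2 == pytest.approx(max(res.tau2, 0.0), rel=1e-10, abs=1e-12)
            if res.tau2 >= 0:
                assert re.mu_hat == pytest.approx(res.mean_effect_re, rel=1e-10)


class TestProperties:
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_pooled_mean_is_convex_combination(self, seed, k):
        rng = np.random.default_rng(seed)
        eff = random_instance(rng, k)
        ys = [e.y for e in eff]
        for res in (mp.fixed_effect_pool(eff), mp.random_effects_pool(eff)):
            assert min(ys) - 1e-12 <= res.mu_hat <= max(ys) + 1e-12
            assert sum(res.weights) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_random_effects_never_more_precise_than_fixed(self, seed, k):
        rng = np.random.default_rng(seed)
        eff = random_instance(rng, k)
        fe, re = mp.fixed_effect_pool(eff), mp.random_effects_pool(eff)
        assert re.var_mu >= fe.var_mu - 1e-15
        if re.tau2 == 0.0:
            assert re.var_mu == pytest.approx(fe.var_mu, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        eff = random_instance(rng, 8)
        perm = list(rng.permutation(8))
        shuffled = [eff[i] for i in perm]
        a, b = mp.random_effects_pool(eff), mp.random_effects_pool(shuffled)
        assert b.mu_hat == pytest.approx(a.mu_hat, rel=1e-12)
        assert b.var_mu == pytest.approx(a.var_mu, rel=1e-12)
        assert b.Q == pytest.approx(a.Q, rel=1e-12)
        assert [b.weights[b.study_ids.index(s)] for s in a.study_ids] == pytest.approx(
            list(a.weights), rel=1e-12
        )
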