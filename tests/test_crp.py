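"""Conjugate kernel: CRP prior, color and count predictives, statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import invgamma, norm, t as student_t

from numerest import (CategoryStats, Hyperparameters, color_predictive,
                      count_predictive_logpdf, crp_prior, downdate_stats,
                      posterior_params, update_stats)
from numerest.crp import posterior_params_stats


def random_stats(rng, hp, n_max=8):
    st_ = CategoryStats(hp.n_colors)
    for _ in range(rng.integers(0, n_max + 1)):
        st_ = update_stats(st_, float(rng.normal(3, 6)),
                           int(rng.integers(1, hp.n_colors + 1)))
    return st_


class TestCrpPrior:
    def test_first_customer(self):
        np.testing.assert_allclose(crp_prior([], 7.3), [1.0])

    def test_arithmetic(self):
        np.testing.assert_allclose(crp_prior([3], 1.0), [0.75, 0.25])
        np.testing.assert_allclose(crp_prior([2, 1], 0.0), [2 / 3, 1 / 3, 0.0])

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            crp_prior([2], -0.1)

    @given(sizes=st.lists(st.integers(1, 40), max_size=8),
           alpha=st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, sizes, alpha):
        p = crp_prior(sizes, alpha)
        assert p.shape == (len(sizes) + 1,)
        assert np.all(p >= 0)
        assert math.isclose(p.sum(), 1.0, abs_tol=1e-12)


class TestColorPredictive:
    def test_uniform_on_empty(self):
        hp = Hyperparameters(lam=1.0, n_colors=3)
        assert color_predictive(CategoryStats(3), 2, hp) == pytest.approx(1 / 3)

    def test_counts_arithmetic(self):
        hp = Hyperparameters(lam=1.0, n_colors=3)
        st_ = CategoryStats(3)
        for _ in range(5):
            st_ = update_stats(st_, 0.0, 1)
        assert color_predictive(st_, 1, hp) == pytest.approx(0.75)

    def test_sums_to_one(self, rng):
        hp = Hyperparameters(lam=0.7, n_colors=4)
        st_ = random_stats(rng, hp)
        total = sum(color_predictive(st_, c, hp) for c in range(1, 5))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_color(self):
        hp = Hyperparameters()
        with pytest.raises(ValueError):
            color_predictive(CategoryStats(3), 4, hp)


class TestPosteriorParams:
    def test_empty_category_reduces_to_prior(self):
        hp = Hyperparameters(a0=3.0, b0=7.0, eta0=2.0, mu0=4.0)
        pp = posterior_params(0, 0.0, 0.0, hp)
        assert pp.mu_hat == pytest.approx(4.0)
        assert pp.eta == pytest.approx(2.0)
        assert pp.a == pytest.approx(1.5)
        assert pp.b == pytest.approx(7.0)

    def test_single_observation_hand_arithmetic(self):
        # one obs x=10 with mu0=0, eta0=1, a0=1, b0=10:
        # mu_hat=5, eta=2, a=1, b = 10 + 0 + 1*1*100/4 = 35
        hp = Hyperparameters(a0=1.0, b0=10.0, eta0=1.0, mu0=0.0)
        st_ = update_stats(CategoryStats(3), 10.0, 2)
        pp = posterior_params_stats(st_, hp)
        assert (pp.mu_hat, pp.eta, pp.a, pp.b) == pytest.approx((5, 2, 1, 35))

    def test_strong_prior_pins_mean(self, rng):
        hp = Hyperparameters(eta0=1e9, mu0=-3.0)
        st_ = random_stats(rng, hp, n_max=6)
        pp = posterior_params_stats(st_, hp)
        assert pp.mu_hat == pytest.approx(-3.0, abs=1e-6)


class TestSufficientStats:
    def test_single_update(self):
        st_ = update_stats(CategoryStats(3), 7.0, 2)
        assert st_.M == 1 and st_.N_c.tolist() == [0, 1, 0]
        assert st_.mean_x == 7.0 and st_.sse_x == 0.0

    def test_update_downdate_roundtrip(self, rng):
        st_ = random_stats(rng, Hyperparameters(), n_max=6)
        before = (st_.M, st_.N_c.copy(), st_.mean_x, st_.sse_x)
        st2 = downdate_stats(update_stats(st_, 11.5, 3), 11.5, 3)
        assert st2.M == before[0]
        assert st2.N_c.tolist() == before[1].tolist()
        assert st2.mean_x == pytest.approx(before[2], abs=1e-10)
        assert st2.sse_x == pytest.approx(before[3], abs=1e-10)

    def test_many_updates_match_batch(self, rng):
        xs = rng.normal(50, 12, size=1000)
        cs = rng.integers(1, 4, size=1000)
        st_ = CategoryStats(3)
        for x, c in zip(xs, cs):
            st_ = update_stats(st_, float(x), int(c))
        assert st_.mean_x == pytest.approx(xs.mean(), abs=1e-8)
        assert st_.sse_x == pytest.approx(((xs - xs.mean()) ** 2).sum(),
                                          rel=1e-10)

    def test_downdate_empty_raises(self):
        with pytest.raises(RuntimeError):
            downdate_stats(CategoryStats(3), 1.0, 1)


class TestCountPredictive:
    def test_symmetry(self, rng):
        hp = Hyperparameters()
        st_ = random_stats(rng, hp)
        pp = posterior_params_stats(st_, hp)
        for d in (0.5, 3.0, 11.0):
            assert count_predictive_logpdf(pp.mu_hat + d, st_, hp) == \
                pytest.approx(count_predictive_logpdf(pp.mu_hat - d, st_, hp))

    def test_empty_category_prior_predictive(self):
        # a0=2, b0=10, eta0=1, mu0=0 -> t with 2 dof, scale sqrt(20)
        hp = Hyperparameters(a0=2.0, b0=10.0, eta0=1.0, mu0=0.0)
        ref = student_t(df=2, loc=0.0, scale=math.sqrt(20.0))
        for x in (-9.0, 0.0, 2.5, 40.0):
            assert count_predictive_logpdf(x, CategoryStats(3), hp) == \
                pytest.approx(ref.logpdf(x), abs=1e-12)

    def test_integrates_to_one(self, rng):
        hp = Hyperparameters(a0=1.5, b0=10.0, eta0=0.3, mu0=2.0)
        st_ = random_stats(rng, hp)
        val, err = integrate.quad(
            lambda x: math.exp(float(count_predictive_logpdf(x, st_, hp))),
            -np.inf, np.inf, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_nig_marginalization(self, rng):
        """The predictive t must equal the numerical marginalization of
        (mu, sigma^2) under the NIG posterior: integrate the Gaussian
        compound N(x; mu_hat, s2*(1+1/eta)) against IG(s2; a, b)."""
        hp = Hyperparameters(a0=2.5, b0=10.0, eta0=0.8, mu0=1.0)
        for _ in range(8):
            st_ = random_stats(rng, hp)
            pp = posterior_params_stats(st_, hp)
            x = float(rng.normal(0, 8))
            oracle, _ = integrate.quad(
                lambda s2: norm.pdf(x, pp.mu_hat, np.sqrt(s2 * (1 + 1 / pp.eta)))
                * invgamma.pdf(s2, pp.a, scale=pp.b),
                0, np.inf, limit=300)
            mine = math.exp(float(count_predictive_logpdf(x, st_, hp)))
            assert mine == pytest.approx(oracle, abs=1e-6)

    def test_consistency_large_sample(self, rng):
        hp = Hyperparameters(mu0=0.0)
        xs = rng.normal(42.0, 6.0, size=10_000)
        st_ = CategoryStats(3)
        for x in xs:
            st_ = update_stats(st_, float(x), 1)
        pp = posterior_params_stats(st_, hp)
        assert pp.mu_hat == pytest.approx(42.0, abs=0.3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            count_predictive_logpdf(np.nan, CategoryStats(3), Hyperparameters())


def joint_log_predictive(observations, hp):
    """Sequential joint log predictive of (x, c) pairs in one category."""
    st_ = CategoryStats(hp.n_colors)
    total = 0.0
    for x, c in observations:
        total += math.log(color_predictive(st_, c, hp))
        total += float(count_predictive_logpdf(x, st_, hp))
        st_ = update_stats(st_, x, c)
    return total


def test_exchangeability(rng):
    """The joint predictive of a category's members is order-invariant."""
    hp = Hyperparameters(a0=1.2, b0=10.0, eta0=0.4, mu0=3.0)
    obs = [(float(rng.normal(0, 10)), int(rng.integers(1, 4))) for _ in range(6)]
    ref = joint_log_predictive(obs, hp)
    for _ in range(10):
        perm = [obs[i] for i in rng.permutation(len(obs))]
        assert joint_log_predictive(perm, hp) == pytest.approx(ref, abs=1e-10)


def test_hyperparameters_json_roundtrip():
    hp = Hyperparameters(alpha=2.5, sigma_y=3.0)
    assert Hyperparameters.from_json(hp.to_json()) == hp


@pytest.mark.parametrize("field,value", [
    ("alpha", -1.0), ("a0", 0.0), ("b0", -2.0), ("eta0", 0.0),
    ("lam", 0.0), ("sigma_y", 0.0), ("n_colors", 1),
])
def test_hyperparameter_validation(field, value):
    with pytest.raises(ValueError):
        Hyperparameters(**{field: value})
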