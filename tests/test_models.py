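"""Likelihoods, transforms and prior construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from glmmscore import (DGPConfig, ModelSpec, ParamState, PriorSpec,
                       arcsinh_inverse, arcsinh_transform, count_cdf,
                       count_logpmf, derive_gamma_prior,
                       generate_nb_longitudinal, linear_predictor,
                       loglik_obs, vst_negbin)


def _state(beta, b, **kw):
    return ParamState(beta=np.asarray(beta, dtype=float),
                      b=np.atleast_2d(np.asarray(b, dtype=float)), **kw)


@pytest.fixture(scope="module")
def demo_data():
    return generate_nb_longitudinal(DGPConfig(n_per_group=3, seed=1))


class TestLinearPredictor:
    def test_zero_parameters_give_zero(self, demo_data):
        spec = ModelSpec("poisson", "I", "main_interaction")
        st0 = _state(np.zeros(4), np.zeros((6, 1)))
        assert np.allclose(linear_predictor(st0, demo_data, spec), 0.0)

    def test_arithmetic_example(self, demo_data):
        # beta=(1, -0.19, 0, -0.17), x=1, t=3 -> eta = -0.08
        spec = ModelSpec("poisson", "I", "main_interaction")
        s = _state([1.0, -0.19, 0.0, -0.17], np.zeros((6, 1)))
        eta = linear_predictor(s, demo_data, spec)
        tab = demo_data.table
        row = np.flatnonzero((tab["group"] == 1) & (tab["time"] == 3.0))[0]
        assert eta[row] == pytest.approx(-0.08, abs=1e-12)

    def test_intercept_only_nests_in_intercept_slope(self, demo_data):
        sI = ModelSpec("poisson", "I", "pre_study")
        sIS = ModelSpec("poisson", "IS", "pre_study")
        beta = np.array([0.7, -0.2, -0.1])
        b0 = np.linspace(-0.4, 0.4, 6)
        etaI = linear_predictor(_state(beta, b0[:, None]), demo_data, sI)
        bIS = np.column_stack([b0, np.zeros(6)])
        etaIS = linear_predictor(_state(beta, bIS), demo_data, sIS)
        assert np.allclose(etaI, etaIS)

    def test_dimension_mismatch(self, demo_data):
        spec = ModelSpec("poisson", "I", "main_interaction")
        with pytest.raises(ValueError):
            linear_predictor(_state([1.0, 2.0], np.zeros((6, 1))),
                             demo_data, spec)


class TestObservationLoglik:
    def test_poisson_at_zero(self):
        s = _state([0.0], np.zeros((1, 1)))
        ll = loglik_obs(s, 0, 0.0, ModelSpec("poisson"))  # mu = 1
        assert ll == pytest.approx(-1.0)

    def test_nb_k1_is_geometric(self):
        spec = ModelSpec("nb")
        for mu in (0.3, 1.0, 7.5):
            s = _state([0.0], np.zeros((1, 1)), k=1.0)
            ll = loglik_obs(s, 0, np.log(mu), spec)
            assert np.exp(ll) == pytest.approx(1.0 / (1.0 + mu), rel=1e-12)

    def test_nb_poisson_limit_sup_norm(self):
        y = np.arange(51)
        eta = np.log(4.0)
        nb = count_logpmf(y, eta, "nb", k=1e6)
        po = count_logpmf(y, eta, "poisson")
        assert np.max(np.abs(np.exp(nb) - np.exp(po))) < 1e-4

    def test_zip_zero_mass(self):
        # Pi0 = 0.09 (ZIP posterior-mean scale), mu = 2
        s = _state([0.0], np.zeros((1, 1)), pi0=0.09)
        ll = loglik_obs(s, 0, np.log(2.0), ModelSpec("zip"))
        assert np.exp(ll) == pytest.approx(0.09 + 0.91 * np.exp(-2.0),
                                           rel=1e-12)

    def test_non_integer_count_rejected(self):
        s = _state([0.0], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            loglik_obs(s, 1.5, 0.0, ModelSpec("poisson"))

    def test_nmm_is_gaussian_on_arcsinh_scale(self):
        s = _state([0.0], np.zeros((1, 1)), sigma_eps=0.5)
        y = 7.0
        ll = loglik_obs(s, y, 1.2, ModelSpec("nmm_arcsinh"))
        want = stats.norm.logpdf(np.arcsinh(y), loc=1.2, scale=0.5)
        assert ll == pytest.approx(want, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(0.3, 50), mu=st.floats(0.05, 30),
           pi0=st.floats(0, 0.8),
           family=st.sampled_from(["poisson", "nb", "zip", "zinb"]))
    def test_pmf_sums_to_one(self, k, mu, pi0, family):
        y = np.arange(0, int(mu + 12 * np.sqrt(mu * (1 + mu / k)) + 60))
        lp = count_logpmf(y, np.log(mu), family, k=k, pi0=pi0)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(0.5, 40), mu=st.floats(0.1, 20))
    def test_nb_mean_variance_identities(self, k, mu):
        y = np.arange(0, int(mu + 30 * np.sqrt(mu * (1 + mu / k)) + 300))
        w = np.exp(count_logpmf(y, np.log(mu), "nb", k=k))
        m = (w * y).sum()
        v = (w * y ** 2).sum() - m ** 2
        p = k / (k + mu)
        assert m == pytest.approx(k * (1 - p) / p, rel=1e-5)
        assert v == pytest.approx(mu + mu ** 2 / k, rel=1e-4)

    def test_zid_with_zero_mass_equals_base(self):
        y = np.arange(30)
        for fam, base in (("zip", "poisson"), ("zinb", "nb")):
            a = count_logpmf(y, 0.8, fam, k=2.0, pi0=0.0)
            b = count_logpmf(y, 0.8, base, k=2.0)
            assert np.array_equal(a, b)

    def test_count_cdf_matches_scipy(self):
        y = np.arange(-1, 25)
        mu, k, pi0 = 3.5, 2.0, 0.2
        assert np.allclose(count_cdf(y, np.log(mu), "poisson"),
                           stats.poisson.cdf(y, mu))
        assert np.allclose(count_cdf(y, np.log(mu), "nb", k=k),
                           stats.nbinom.cdf(y, k, k / (k + mu)))
        zip_cdf = count_cdf(y, np.log(mu), "zip", pi0=pi0)
        want = np.where(y < 0, 0.0, pi0 + (1 - pi0) * stats.poisson.cdf(y, mu))
        assert np.allclose(zip_cdf, want)


class TestTransforms:
    def test_arcsinh_values_and_roundtrip(self):
        assert arcsinh_transform(0.0) == 0.0
        assert arcsinh_transform(1.0) == pytest.approx(np.log(1 + np.sqrt(2)))
        for y in (0.0, 3.0, 25.0):
            assert arcsinh_inverse(arcsinh_transform(y)) == pytest.approx(
                y, abs=1e-12)

    def test_vst_zero_and_errors(self):
        assert vst_negbin(0.0, 1.0) == 0.0
        assert vst_negbin(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            vst_negbin(4.0, -0.1)
        with pytest.raises(ValueError):
            vst_negbin(-1.0, 0.1)

    def test_vst_matches_quadrature(self):
        for z, y in ((1.0, 4.0), (0.25, 9.0), (3.0, 2.0)):
            oracle, _ = integrate.quad(
                lambda u: 1.0 / np.sqrt(u * (z * u + 1.0)), 0.0, y)
            assert vst_negbin(y, z) == pytest.approx(oracle, abs=1e-8)

    def test_vst_poisson_limit_proportional_to_sqrt(self):
        vals = np.array([vst_negbin(y, 1e-8) / np.sqrt(y)
                         for y in (1.0, 4.0, 9.0)])
        assert np.allclose(vals, vals[0], rtol=1e-4)


class TestGammaPriorDerivation:
    def test_published_cauchy_construction(self):
        a, b = derive_gamma_prior(0.6, 0.5)
        assert a == 0.5
        assert b == pytest.approx(0.001115, abs=5e-7)
        assert b / a == pytest.approx(0.00223, abs=5e-6)

    def test_rate_scales_with_range_squared(self):
        _, b1 = derive_gamma_prior(0.6, 0.5)
        _, b2 = derive_gamma_prior(1.2, 0.5)
        assert b2 == pytest.approx(4 * b1, rel=1e-12)

    def test_against_independent_quantile_oracle(self):
        # invert the t CDF by quadrature + root finding, never via ppf
        df = 2.0
        dens = stats.t(df).pdf

        def cdf(x):
            val, _ = integrate.quad(dens, -np.inf, x)
            return val

        q975 = optimize.brentq(lambda x: cdf(x) - 0.975, 0.1, 50.0,
                               xtol=1e-10)
        a, b = derive_gamma_prior(0.6, 1.0)
        assert b == pytest.approx(1.0 * (0.6 / q975) ** 2, rel=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            derive_gamma_prior(-0.1, 0.5)
        with pytest.raises(ValueError):
            derive_gamma_prior(0.6, 0.0)


class TestSpecsAndPriors:
    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(wishart_r=1.0)
        with pytest.raises(ValueError):
            PriorSpec(wishart_R=((1.0, 2.0), (2.0, 1.0)))
        with pytest.raises(ValueError):
            PriorSpec(intercept_prec_a=0.0)

    def test_modelspec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("gamma")
        with pytest.raises(ValueError):
            ModelSpec("nb", random_structure="X")
        assert ModelSpec("nb").label() == "NB(I)"
        assert ModelSpec("nmm_arcsinh", "IS").label() == "arcsinh(IS)"

    def test_state_validation(self):
        s = ParamState(beta=np.zeros(2), b=np.zeros((1, 1)), tau_b0=-1.0)
        with pytest.raises(ValueError):
            s.validate()
        s2 = ParamState(beta=np.zeros(2), b=np.zeros((1, 2)), tau_b0=1.0,
                        tau_b1=1.0, rho=1.5)
        with pytest.raises(ValueError):
            s2.validate()
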