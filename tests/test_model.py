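"""Generative process: observation model, priors, and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from intervalconsensus.model import (
    ConsensusParam,
    Hyperparams,
    ItemParams,
    PersonParams,
    bounded_consensus_to_unbounded,
    consensus_prior_dirichlet_logpdf,
    consensus_prior_logpdf,
    hier_prior_logpdf,
    loglik_obs,
    response_cov,
    response_mean,
    sample_consensus,
    sample_items,
    sample_persons,
    simulate_responses,
)


def _person(E_loc=1.0, E_wid=1.0, a=1.0, b_loc=0.0, b_wid=0.0):
    return PersonParams(E_loc, E_wid, a, b_loc, b_wid)


def _item(lam_loc=1.0, lam_wid=1.0, rho=0.0):
    return ItemParams(lam_loc, lam_wid, rho)


class TestResponseMoments:
    @pytest.mark.parametrize(
        "T, a, b, expected",
        [
            ((1.0, -0.5), 1.0, (0.0, 0.0), (1.0, -0.5)),
            ((1.0, -0.5), 1.5, (0.0, 0.0), (1.5, -0.5)),
            ((0.0, 0.0), 2.0, (0.3, -0.2), (0.3, -0.2)),
        ],
    )
    def test_mean_examples(self, T, a, b, expected):
        mean = response_mean(ConsensusParam(*T), _person(a=a, b_loc=b[0], b_wid=b[1]))
        np.testing.assert_allclose(mean, expected)

    @pytest.mark.parametrize(
        "E, a, rho, expected",
        [
            ((1, 1), 1.0, 0.0, np.eye(2)),
            ((2, 1), 1.0, 0.0, np.diag([0.25, 1.0])),
            ((1, 1), 2.0, 0.5, [[4.0, 1.0], [1.0, 1.0]]),
        ],
    )
    def test_cov_examples(self, E, a, rho, expected):
        cov = response_cov(_person(E_loc=E[0], E_wid=E[1], a=a), _item(rho=rho))
        np.testing.assert_allclose(cov, expected)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    @given(
        st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5),
        st.floats(0.1, 5), st.floats(0.1, 5), st.floats(-0.95, 0.95),
    )
    @settings(max_examples=100, deadline=None)
    def test_cov_positive_definite(self, el, ew, a, ll, lw, rho):
        cov = response_cov(_person(E_loc=el, E_wid=ew, a=a), _item(ll, lw, rho))
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_scaling_bias_couples_mean_and_sd(self):
        # multiplying a by k multiplies both the location mean deviation and
        # the location SD by k, leaving the width untouched
        T = ConsensusParam(0.8, -0.3)
        for k in (2.0, 0.5):
            m1 = response_mean(T, _person(a=1.0))
            mk = response_mean(T, _person(a=k))
            c1 = response_cov(_person(a=1.0), _item())
            ck = response_cov(_person(a=k), _item())
            assert mk[0] == pytest.approx(k * m1[0])
            assert mk[1] == pytest.approx(m1[1])
            assert np.sqrt(ck[0, 0]) == pytest.approx(k * np.sqrt(c1[0, 0]))
            assert ck[1, 1] == pytest.approx(c1[1, 1])

    def test_precision_parameters_are_inverted(self):
        # larger proficiency/discernibility -> smaller error SD
        base = response_cov(_person(), _item())
        for kwargs in ({"E_loc": 2.0}, {"E_wid": 2.0}):
            assert np.trace(response_cov(_person(**kwargs), _item())) < np.trace(base)
        for kwargs in ({"lam_loc": 2.0}, {"lam_wid": 2.0}):
            assert np.trace(response_cov(_person(), _item(**kwargs))) < np.trace(base)


class TestLoglik:
    def test_at_mode_unit_cov(self):
        T = ConsensusParam(0.3, -0.2)
        ll = loglik_obs(np.array([0.3, -0.2]), T, _person(), _item())
        assert ll == pytest.approx(-np.log(2 * np.pi))

    def test_rho_zero_factorises(self):
        T = ConsensusParam(0.5, 0.1)
        p, it = _person(E_loc=1.5, a=1.2, b_loc=0.1), _item(lam_loc=0.8, lam_wid=1.3)
        y = np.array([0.7, -0.4])
        joint = loglik_obs(y, T, p, it)
        sd_loc = p.a / (p.E_loc * it.lam_loc)
        sd_wid = 1 / (p.E_wid * it.lam_wid)
        mean = response_mean(T, p)
        sep = stats.norm.logpdf(y[0], mean[0], sd_loc) + stats.norm.logpdf(
            y[1], mean[1], sd_wid
        )
        assert joint == pytest.approx(sep, abs=1e-12)

    def test_matches_quadrature_normalisation(self):
        # the density exponentiated from loglik_obs integrates to 1
        rng = np.random.default_rng(3)
        T = ConsensusParam(0.4, -0.6)
        p = _person(E_loc=1.3, E_wid=0.7, a=1.4, b_loc=0.2, b_wid=-0.1)
        it = _item(lam_loc=1.1, lam_wid=0.9, rho=0.6)

        def dens(yl, yw):
            return np.exp(loglik_obs(np.array([yl, yw]), T, p, it))

        val, err = integrate.dblquad(dens, -10, 10, -8, 8, epsabs=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_singular_correlation_rejected(self):
        with pytest.raises(ValueError):
            ItemParams(1.0, 1.0, 1.0)


class TestConsensusPriors:
    def test_uniform_priors_contribute_zero(self):
        hp = Hyperparams(alpha_w=1, beta_w=1, alpha_l=1, beta_l=1)
        assert consensus_prior_logpdf(0.3, 0.5, hp) == pytest.approx(0.0)

    def test_uniform_location_term_constant(self):
        hp = Hyperparams(alpha_l=1.0, beta_l=1.0)
        vals = [consensus_prior_logpdf(0.3, ls, hp) for ls in (0.1, 0.5, 0.9)]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            consensus_prior_logpdf(1.0, 0.5, Hyperparams())

    def test_bounded_to_unbounded_construction(self):
        # lower = lamstar*(1-w); origin when the induced composition is uniform
        z = bounded_consensus_to_unbounded(1 / 3, 0.5)
        np.testing.assert_allclose(z, (0.0, 0.0), atol=1e-12)

    def test_dirichlet_uniform_is_log2(self):
        for m in [(0.2, 0.3, 0.5), (0.1, 0.8, 0.1)]:
            assert consensus_prior_dirichlet_logpdf(m, (1, 1, 1)) == pytest.approx(
                np.log(2.0)
            )

    def test_dirichlet_symmetric_permutation_invariance(self):
        alpha = (2.5, 2.5, 2.5)
        m = np.array([0.2, 0.3, 0.5])
        vals = {
            round(consensus_prior_dirichlet_logpdf(m[list(p)], alpha), 12)
            for p in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
        }
        assert len(vals) == 1

    def test_prior_predictive_width_moments(self):
        hp = Hyperparams()
        rng = np.random.default_rng(11)
        w, lamstar, T = sample_consensus(100_000, hp, rng)
        assert w.mean() == pytest.approx(hp.alpha_w / (hp.alpha_w + hp.beta_w), abs=0.005)
        # conditional-uniform location: lamstar | w is Uniform(0,1)
        assert stats.kstest(lamstar, "uniform").pvalue > 0.001


class TestHierPrior:
    def test_additivity_at_reference_values(self):
        hp = Hyperparams()
        p = _person()
        it = _item(rho=0.0)
        lp = hier_prior_logpdf(p, it, hp)
        expected = (
            stats.norm.logpdf(0.0, 0.0, hp.sigma_E[0])
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_E[1])
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_lam[0])
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_lam[1])
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_a)
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_b[0])
            + stats.norm.logpdf(0.0, 0.0, hp.sigma_b[1])
            + stats.beta.logpdf(0.5, hp.rho_shape, hp.rho_shape)
            - np.log(2.0)
        )
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_rho_prior_uniform_at_shape_one(self):
        hp = Hyperparams(rho_shape=1.0)
        p = _person()
        for rho in (-0.7, 0.0, 0.9):
            it = _item(rho=rho)
            lp = hier_prior_logpdf(p, it, hp)
            # rho contributes the constant -ln 2 regardless of its value
            assert lp == pytest.approx(
                hier_prior_logpdf(p, _item(rho=0.0), hp), abs=1e-12
            )

    def test_identifiability_constraints_hold_exactly(self):
        hp = Hyperparams()
        rng = np.random.default_rng(5)
        persons = sample_persons(2000, hp, rng)
        items = sample_items(500, hp, rng)
        assert persons.a.mean() == pytest.approx(1.0, abs=1e-12)
        assert persons.b_loc.mean() == pytest.approx(0.0, abs=1e-12)
        assert persons.b_wid.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.log(items.lam_loc).mean() == pytest.approx(0.0, abs=1e-12)
        assert np.log(items.lam_wid).mean() == pytest.approx(0.0, abs=1e-12)


class TestSimulation:
    def test_fixed_seed_reproducible(self, small_dataset):
        data, truth = small_dataset
        again = simulate_responses(
            truth["T"], truth["persons"], truth["items"], seed=123
        )
        twice = simulate_responses(
            truth["T"], truth["persons"], truth["items"], seed=123
        )
        assert again.equals(twice)

    def test_empty_design_rejected(self, small_dataset):
        _, truth = small_dataset
        with pytest.raises(ValueError, match="design"):
            simulate_responses(truth["T"], truth["persons"], truth["items"], design=[])

    def test_high_precision_limit_recovers_biased_mean(self):
        rng = np.random.default_rng(9)
        T = ConsensusParam(np.array([0.5]), np.array([-0.4]))
        p = PersonParams([1e6], [1e6], [1.3], [0.2], [-0.1])
        it = ItemParams([1.0], [1.0], [0.0])
        data = simulate_responses(T, p, it, rng=rng)
        assert data["loc"].iloc[0] == pytest.approx(1.3 * 0.5 + 0.2, abs=1e-4)
        assert data["wid"].iloc[0] == pytest.approx(-0.4 - 0.1, abs=1e-4)

    def test_sample_covariance_matches_model(self):
        rng = np.random.default_rng(10)
        T = ConsensusParam(np.array([0.2]), np.array([-0.3]))
        p = PersonParams([1.5], [0.8], [1.2], [0.1], [0.0])
        it = ItemParams([0.9], [1.4], [0.5])
        design = [(0, 0)] * 50_000
        data = simulate_responses(T, p, it, design=design, rng=rng)
        emp = np.cov(data["loc"], data["wid"])
        expected = response_cov(p, it)[0]
        np.testing.assert_allclose(emp, expected, rtol=0.05, atol=0.005)

    def test_responses_are_valid_intervals(self, small_dataset):
        data, _ = small_dataset
        assert ((data["lower"] >= 0) & (data["lower"] <= data["upper"])).all()
        assert (data["upper"] <= 1).all()
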