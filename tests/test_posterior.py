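"""Unconstrained posterior: gradients, parameterisation, variants."""

import numpy as np
import pytest

from intervalconsensus._posterior import (
    ICMPosterior,
    PosteriorConfig,
    _helmert_contract,
    _helmert_expand,
)
from intervalconsensus.model import (
    ConsensusParam,
    ItemParams,
    PersonParams,
    loglik_obs,
)
from intervalconsensus.simstudy import GenerationConfig, simulate_condition

VARIANTS = [
    PosteriorConfig(),
    PosteriorConfig(include_a=False),
    PosteriorConfig(include_b_loc=False),
    PosteriorConfig(include_b_wid=False),
    PosteriorConfig(include_a=False, include_b_loc=False, include_b_wid=False),
    PosteriorConfig(estimate_correlations=True),
]


@pytest.fixture(scope="module")
def tiny_posterior_inputs():
    data, _ = simulate_condition(6, 4, 0, GenerationConfig())
    y = data[["loc", "wid"]].to_numpy()
    oi = data["respondent_id"].astype("category").cat.codes.to_numpy()
    oj = data["item_id"].astype("category").cat.codes.to_numpy()
    return y, oi, oj, 6, 4


class TestHelmertBasis:
    @pytest.mark.parametrize("m", [1, 2, 7, 30])
    def test_expansion_sums_to_zero_and_is_orthonormal(self, m):
        rng = np.random.default_rng(m)
        z = rng.standard_normal(m)
        full = _helmert_expand(z)
        assert full.shape == (m + 1,)
        assert abs(full.sum()) < 1e-12
        np.testing.assert_allclose(_helmert_contract(full), z, atol=1e-12)
        # isometry: the free coordinates carry the full squared norm
        assert full @ full == pytest.approx(z @ z, rel=1e-12)

    def test_adjoint_identity(self):
        rng = np.random.default_rng(0)
        z, g = rng.standard_normal(5), rng.standard_normal(6)
        # <H z, g> == <z, H^T g>
        assert _helmert_expand(z) @ g == pytest.approx(
            z @ _helmert_contract(g), rel=1e-12
        )


class TestGradients:
    @pytest.mark.parametrize("cfg", VARIANTS)
    def test_matches_finite_differences(self, tiny_posterior_inputs, cfg):
        y, oi, oj, N, J = tiny_posterior_inputs
        post = ICMPosterior(y, oi, oj, N, J, cfg)
        rng = np.random.default_rng(1)
        theta = post.random_init(rng, 1.0)
        _, grad = post.logp_and_grad(theta)
        eps = 1e-6
        for k in range(0, post.dim, 3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            fd = (post.logp_and_grad(tp)[0] - post.logp_and_grad(tm)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    @pytest.mark.parametrize("cfg", VARIANTS)
    def test_compiled_kernel_matches_reference(self, tiny_posterior_inputs, cfg):
        y, oi, oj, N, J = tiny_posterior_inputs
        post = ICMPosterior(y, oi, oj, N, J, cfg)
        rng = np.random.default_rng(2)
        for _ in range(3):
            theta = post.random_init(rng, 1.5)
            lp_ref, g_ref = post.logp_and_grad(theta)
            lp_fast, g_fast = post.logp_and_grad_fast(theta)
            assert lp_fast == pytest.approx(lp_ref, rel=1e-10, abs=1e-8)
            np.testing.assert_allclose(g_fast, g_ref, rtol=1e-9, atol=1e-9)


class TestConstrainedParams:
    def test_identifiability_constraints(self, tiny_posterior_inputs):
        y, oi, oj, N, J = tiny_posterior_inputs
        post = ICMPosterior(y, oi, oj, N, J)
        theta = post.random_init(np.random.default_rng(3), 1.0)
        c = post.constrained(theta)
        assert c["a"].mean() == pytest.approx(1.0, abs=1e-12)
        assert c["b_loc"].mean() == pytest.approx(0.0, abs=1e-12)
        assert c["b_wid"].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.log(c["lam_loc"]).mean() == pytest.approx(0.0, abs=1e-12)
        assert np.all(c["E_loc"] > 0) and np.all(c["lam_wid"] > 0)
        assert np.all((c["w"] > 0) & (c["w"] < 1))
        assert np.all(np.abs(c["rho"]) < 1)

    def test_dropping_biases_removes_free_parameters(self, tiny_posterior_inputs):
        y, oi, oj, N, J = tiny_posterior_inputs
        full = ICMPosterior(y, oi, oj, N, J, PosteriorConfig())
        reduced = ICMPosterior(
            y, oi, oj, N, J, PosteriorConfig(include_a=False, include_b_loc=False)
        )
        assert reduced.dim < full.dim
        c = reduced.constrained(reduced.random_init(np.random.default_rng(0)))
        np.testing.assert_array_equal(c["a"], np.ones(N))
        np.testing.assert_array_equal(c["b_loc"], np.zeros(N))

    def test_nested_variant_likelihood_consistency(self, tiny_posterior_inputs):
        """Dropping bias terms equals the full likelihood at constrained values."""
        y, oi, oj, N, J = tiny_posterior_inputs
        rng = np.random.default_rng(8)
        T = ConsensusParam(rng.normal(0, 0.5, J), rng.normal(0, 0.5, J))
        E_loc, E_wid = np.exp(rng.normal(0, 0.3, (2, N)))
        lam = np.exp(rng.normal(0, 0.3, (2, J)))
        items = ItemParams(lam[0], lam[1], rng.uniform(-0.5, 0.5, J))
        free = PersonParams(E_loc, E_wid, np.ones(N), np.zeros(N), np.zeros(N))
        ll_full = sum(
            loglik_obs(
                y[k],
                ConsensusParam(T.T_loc[oj[k]], T.T_wid[oj[k]]),
                PersonParams(
                    E_loc[oi[k]], E_wid[oi[k]], free.a[oi[k]],
                    free.b_loc[oi[k]], free.b_wid[oi[k]],
                ),
                ItemParams(items.lam_loc[oj[k]], items.lam_wid[oj[k]], items.rho[oj[k]]),
            )
            for k in range(len(y))
        )
        # bias-free likelihood evaluated directly (no a, b terms at all)
        sd_loc = 1.0 / (E_loc[oi] * items.lam_loc[oj])
        sd_wid = 1.0 / (E_wid[oi] * items.lam_wid[oj])
        from intervalconsensus.model import bvn_logpdf

        mean = np.stack([T.T_loc[oj], T.T_wid[oj]], axis=-1)
        ll_reduced = bvn_logpdf(y, mean, sd_loc, sd_wid, items.rho[oj]).sum()
        assert ll_reduced == pytest.approx(ll_full, abs=1e-10)


class TestAsisRejuvenation:
    def test_preserves_centred_quantities(self, tiny_posterior_inputs):
        y, oi, oj, N, J = tiny_posterior_inputs
        post = ICMPosterior(y, oi, oj, N, J)
        rng = np.random.default_rng(4)
        theta = post.random_init(rng, 1.0)
        before = post.constrained(theta)
        after = post.constrained(post.asis_rejuvenate(theta, rng))
        # observable parameters are untouched; hyperparameters move
        for key in ("a", "b_loc", "b_wid", "lam_loc", "lam_wid", "E_loc", "E_wid",
                    "T_loc", "T_wid", "rho"):
            np.testing.assert_allclose(after[key], before[key], atol=1e-10)
        moved = sum(
            not np.allclose(after[k], before[k])
            for k in ("sigma_a", "sigma_E", "sigma_lam", "mu_E")
        )
        assert moved >= 2

    def test_finite_logp_after_rejuvenation(self, tiny_posterior_inputs):
        y, oi, oj, N, J = tiny_posterior_inputs
        post = ICMPosterior(y, oi, oj, N, J)
        rng = np.random.default_rng(5)
        theta = post.random_init(rng, 0.5)
        for _ in range(20):
            theta = post.asis_rejuvenate(theta, rng)
            lp, _ = post.logp_and_grad(theta)
            assert np.isfinite(lp)


def test_requires_minimum_design():
    y = np.zeros((2, 2))
    with pytest.raises(ValueError, match="at least 2"):
        ICMPosterior(y, [0, 0], [0, 1], 1, 2)
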