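import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avib.posteriors import (
    AoeParameters,
    DiagonalGaussian,
    ExpertStack,
    aggregate,
    aoe_aggregate,
    attention_weights,
    kl_to_standard_normal,
    moe_aggregate,
    poe_aggregate,
    pool_aggregate,
    reparameterized_sample,
    stack_experts,
)


class TestKL:
    def test_standard_normal_is_zero(self):
        assert kl_to_standard_normal(DiagonalGaussian.standard(5)) == 0.0

    def test_unit_mean_shift_is_half(self):
        g = DiagonalGaussian(np.array([1.0]), np.array([1.0]))
        assert kl_to_standard_normal(g) == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self, rng, make_gaussian):
        """Closed form within 3 standard errors of E_z~g[ln g − ln N(0,I)]."""
        n = 10**6
        for _ in range(5):
            g = make_gaussian(rng, 4)
            eps = rng.standard_normal((n, 4))
            z = g.mu + g.sigma * eps
            log_q = (-0.5 * eps**2 - np.log(g.sigma) - 0.5 * np.log(2 * np.pi)).sum(1)
            log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(1)
            diffs = log_q - log_p
            se = diffs.std(ddof=1) / np.sqrt(n)
            assert abs(kl_to_standard_normal(g) - diffs.mean()) < 3 * se

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            DiagonalGaussian(np.zeros(2), np.array([1.0, 0.0]))


class TestReparameterization:
    def test_zero_eps_returns_mu(self, rng, make_gaussian):
        g = make_gaussian(rng, 6)
        np.testing.assert_array_equal(reparameterized_sample(g, np.zeros(6)), g.mu)

    def test_standard_normal_returns_eps(self, rng):
        e = rng.normal(size=4)
        np.testing.assert_array_equal(
            reparameterized_sample(DiagonalGaussian.standard(4), e), e
        )

    def test_sampling_moments(self, rng, make_gaussian):
        g = make_gaussian(rng, 3)
        n = 10**5
        zs = np.array([reparameterized_sample(g, e) for e in rng.standard_normal((n, 3))])
        np.testing.assert_array_less(
            np.abs(zs.mean(0) - g.mu), 3 * g.sigma / np.sqrt(n)
        )
        np.testing.assert_allclose(zs.var(0), g.sigma**2, rtol=0.05)

    def test_shape_mismatch_rejected(self, rng, make_gaussian):
        with pytest.raises(ValueError):
            reparameterized_sample(make_gaussian(rng, 3), np.zeros(4))


class TestStacking:
    def test_prior_row_and_order(self):
        e = DiagonalGaussian(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        stack = stack_experts([e])
        np.testing.assert_array_equal(stack.M, [[0, 0], [1, 1]])
        np.testing.assert_array_equal(stack.S, [[1, 1], [2, 2]])
        assert stack.row_roles[0] == "prior"

    def test_m_experts_give_m_plus_one_rows(self, rng, make_gaussian):
        experts = [make_gaussian(rng, 4) for _ in range(5)]
        assert stack_experts(experts).M.shape == (6, 4)

    def test_round_trip(self, rng, make_gaussian):
        experts = [make_gaussian(rng, 4) for _ in range(3)]
        back = stack_experts(experts).experts()
        for a, b in zip(experts, back):
            np.testing.assert_array_equal(a.mu, b.mu)
            np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_empty_and_mixed_dims_rejected(self, rng, make_gaussian):
        with pytest.raises(ValueError):
            stack_experts([])
        with pytest.raises(ValueError):
            stack_experts([make_gaussian(rng, 2), make_gaussian(rng, 3)])


class TestPoE:
    def test_prior_plus_standard_expert_halves_variance(self):
        stack = stack_experts([DiagonalGaussian.standard(3)])
        out = poe_aggregate(stack)
        np.testing.assert_allclose(out.mu, 0.0)
        np.testing.assert_allclose(out.sigma**2, 0.5)

    def test_confident_expert_dominates(self):
        e = DiagonalGaussian(np.array([3.0]), np.array([1e-6]))
        out = poe_aggregate(stack_experts([e]))
        np.testing.assert_allclose(out.mu, 3.0, atol=1e-9)

    def test_matches_quadrature_oracle(self, rng, make_gaussian):
        """PoE mean/variance equal numerical normalization of the product
        density on a fine 1-D grid."""
        for _ in range(20):
            experts = [make_gaussian(rng, 1) for _ in range(2)]
            stack = stack_experts(experts)
            out = poe_aggregate(stack)
            grid = np.linspace(-15, 15, 300001)
            log_dens = -0.5 * grid**2  # prior, unnormalized
            for e in experts:
                log_dens += -0.5 * ((grid - e.mu[0]) / e.sigma[0]) ** 2 - np.log(e.sigma[0])
            dens = np.exp(log_dens - log_dens.max())
            zmass = np.trapezoid(dens, grid)
            mean = np.trapezoid(grid * dens, grid) / zmass
            var = np.trapezoid((grid - mean) ** 2 * dens, grid) / zmass
            assert abs(out.mu[0] - mean) < 1e-6
            assert abs(out.sigma[0] ** 2 - var) < 1e-6

    def test_precision_monotonicity(self, rng, make_gaussian):
        """PoE variance never exceeds the smallest expert variance."""
        for _ in range(10):
            experts = [make_gaussian(rng, 4) for _ in range(rng.integers(1, 5))]
            out = poe_aggregate(stack_experts(experts))
            smallest = np.min([e.sigma**2 for e in experts], axis=0)
            assert np.all(out.sigma**2 <= smallest + 1e-12)


class TestMoE:
    def test_single_expert_equals_that_gaussian(self, rng, make_gaussian):
        e = make_gaussian(rng, 2)
        mix = moe_aggregate(stack_experts([e]))
        z = rng.normal(size=2)
        ref = np.exp(-0.5 * ((z - e.mu) / e.sigma) ** 2) / (e.sigma * np.sqrt(2 * np.pi))
        assert mix.pdf(z) == pytest.approx(float(np.prod(ref)))

    def test_symmetric_experts_have_zero_mean(self):
        a = DiagonalGaussian(np.array([2.0]), np.array([1.0]))
        b = DiagonalGaussian(np.array([-2.0]), np.array([1.0]))
        mix = moe_aggregate(stack_experts([a, b]))
        np.testing.assert_allclose(mix.mean, 0.0)

    def test_density_integrates_to_one(self, rng, make_gaussian):
        experts = [make_gaussian(rng, 1) for _ in range(3)]
        mix = moe_aggregate(stack_experts(experts))
        grid = np.linspace(-20, 20, 40001)
        dens = np.array([mix.pdf(np.array([x])) for x in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_prior_is_excluded(self, rng, make_gaussian):
        e = make_gaussian(rng, 2)
        mix = moe_aggregate(stack_experts([e]))
        assert len(mix.components) == 1


class TestPooling:
    def test_max_and_avg_by_definition(self):
        stack = ExpertStack(
            M=np.array([[1.0, 2.0], [3.0, 0.0]]),
            S=np.ones((2, 2)),
            row_roles=("prior", "e0"),
        )
        np.testing.assert_array_equal(pool_aggregate(stack, "max").mu, [3, 2])
        np.testing.assert_array_equal(pool_aggregate(stack, "avg").mu, [2, 1])

    def test_avg_includes_prior_row(self, rng, make_gaussian):
        e = make_gaussian(rng, 3)
        out = pool_aggregate(stack_experts([e]), "avg")
        np.testing.assert_allclose(out.mu, e.mu / 2)
        np.testing.assert_allclose(out.sigma, (e.sigma + 1) / 2)

    def test_identical_rows_make_modes_agree(self):
        mu, sg = np.full((3, 4), 1.5), np.full((3, 4), 0.7)
        stack = ExpertStack(M=mu, S=sg, row_roles=("prior", "a", "b"))
        mx, av = pool_aggregate(stack, "max"), pool_aggregate(stack, "avg")
        np.testing.assert_allclose(mx.mu, av.mu)
        np.testing.assert_allclose(mx.sigma, av.sigma)


class TestAoE:
    def _params(self, rng, d=4, h=2, **kw):
        return AoeParameters.initialize(d, h, rng, **kw)

    def test_output_sigma_positive(self, rng, make_stack):
        for mode in ("log", "literal"):
            params = self._params(rng, sigma_mode=mode)
            out = aoe_aggregate(make_stack(rng, 3, 4), params)
            assert np.all(out.sigma > 0)

    def test_permutation_invariance(self, rng, make_stack):
        """No positional encoding: permuting expert rows leaves the output
        unchanged (prior row permuted along — rows are an unordered set)."""
        params = self._params(rng)
        for _ in range(20):
            stack = make_stack(rng, 4, 4)
            out = aoe_aggregate(stack, params)
            perm = rng.permutation(5)
            shuffled = ExpertStack(
                M=stack.M[perm], S=stack.S[perm],
                row_roles=tuple(stack.row_roles[i] for i in perm),
            )
            out2 = aoe_aggregate(shuffled, params)
            np.testing.assert_allclose(out.mu, out2.mu, atol=1e-6)
            np.testing.assert_allclose(out.sigma, out2.sigma, atol=1e-6)

    def test_matches_bruteforce_oracle(self, rng, make_stack, oracle):
        """Vectorized AoE equals explicit per-head attention loops."""
        for _ in range(10):
            params = self._params(rng)
            stack = make_stack(rng, 2, 4)
            out = aoe_aggregate(stack, params)
            mu_ref, sigma_ref = oracle.aoe(stack, params)
            np.testing.assert_allclose(out.mu, mu_ref, atol=1e-5)
            np.testing.assert_allclose(out.sigma, sigma_ref, atol=1e-5)

    def test_dimension_mismatch_rejected(self, rng, make_stack):
        with pytest.raises(ValueError):
            aoe_aggregate(make_stack(rng, 2, 6), self._params(rng, d=4))

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            AoeParameters.initialize(5, 2, rng)


class TestAttentionWeights:
    def test_rows_sum_to_one(self, rng, make_stack):
        params = AoeParameters.initialize(4, 2, rng)
        res = attention_weights(make_stack(rng, 3, 4), params)
        w = res["weights"]
        assert w.shape == (2, 4, 4)
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert res["row_roles"][0] == "prior"

    def test_identical_rows_give_uniform_weights(self, rng):
        params = AoeParameters.initialize(4, 2, rng)
        row_mu, row_sg = np.ones(4), np.full(4, 2.0)
        e = DiagonalGaussian(row_mu, row_sg)
        stack = ExpertStack(
            M=np.tile(row_mu, (3, 1)), S=np.tile(row_sg, (3, 1)),
            row_roles=("prior", "a", "b"),
        )
        w = attention_weights(stack, params)["weights"]
        np.testing.assert_allclose(w, 1.0 / 3.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng, make_stack, oracle):
        params = AoeParameters.initialize(4, 2, rng)
        stack = make_stack(rng, 3, 4)
        w = attention_weights(stack, params, branch="mu")["weights"]
        ref = oracle.weights(stack.M, params.wq_mu, params.wk_mu)
        np.testing.assert_allclose(w, ref, atol=1e-6)
        w_s = attention_weights(stack, params, branch="sigma")["weights"]
        ref_s = oracle.weights(np.log(stack.S), params.wq_sigma, params.wk_sigma)
        np.testing.assert_allclose(w_s, ref_s, atol=1e-6)


@settings(deadline=None, max_examples=25)
@given(
    n_experts=st.integers(min_value=1, max_value=8),
    kind=st.sampled_from(["aoe", "poe", "maxpool", "avgpool"]),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_every_aggregator_returns_valid_gaussian(n_experts, kind, seed):
    """Any valid stack of 1–8 experts aggregates to a finite, positive-sigma
    diagonal Gaussian under every single-Gaussian scheme."""
    rng = np.random.default_rng(seed)
    experts = [
        DiagonalGaussian(rng.normal(size=4), np.exp(rng.normal(scale=1.0, size=4)))
        for _ in range(n_experts)
    ]
    stack = stack_experts(experts)
    params = AoeParameters.initialize(4, 2, rng) if kind == "aoe" else None
    out = aggregate(stack, kind, params)
    assert np.all(np.isfinite(out.mu)) and np.all(np.isfinite(out.sigma))
    assert np.all(out.sigma > 0)
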