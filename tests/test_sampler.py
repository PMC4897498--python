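"""Chain runner tests: initialization, bookkeeping, determinism, blocked
execution (bit-equivalence and statistical equivalence), partial-sum
reductions, sub-chain stationarity against independent quadrature, and
parameter recovery on synthetic data."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from ogive.conditionals import (
    sample_theta,
    theta_posterior_params,
    update_items,
    update_Z,
)
from ogive.exceptions import ChainAborted
from ogive.model import ItemParameters, ResponseMatrix, TraitVector
from ogive.sampler import (
    BlockGrid,
    ChainConfig,
    gibbs_step,
    initialize_state,
    reduce_block_sums,
    run_chain,
    run_chain_blocked,
)
from ogive.sampler import _block_stream, _KERNEL_ITEMS, _KERNEL_THETA, _KERNEL_Z
from ogive.summaries import mcse
from ogive.synthetic import GeneratorSpec, simulate_responses


class TestBlockGrid:
    def test_even_partition(self):
        g = BlockGrid.from_shape(5, 5, 500, 20)
        assert g.row_bounds == (0, 100, 200, 300, 400, 500)
        assert g.col_bounds == (0, 4, 8, 12, 16, 20)

    def test_trailing_block_absorbs_remainder(self):
        g = BlockGrid.from_shape(3, 2, 10, 5)
        assert g.row_bounds == (0, 3, 6, 10)
        assert g.col_bounds == (0, 2, 5)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            BlockGrid.from_shape(0, 1, 10, 5)
        with pytest.raises(ValueError):
            BlockGrid.from_shape(11, 1, 10, 5)
        with pytest.raises(ValueError):
            BlockGrid(row_bounds=(0, 5, 3), col_bounds=(0, 2))

    def test_coverage_validation(self):
        g = BlockGrid.from_shape(2, 2, 10, 4)
        with pytest.raises(ValueError, match="covers"):
            g.validate_for(12, 4)


class TestChainConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=10, burn_in=10)
        with pytest.raises(ValueError):
            ChainConfig(iterations=10, thin=0)
        with pytest.raises(ValueError):
            ChainConfig(iterations=10, prior_mode="other")

    def test_round_trip_dict(self):
        cfg = ChainConfig(
            iterations=100,
            burn_in=10,
            seed=4,
            grid=BlockGrid.from_shape(2, 2, 10, 4),
            prior_mode="conjugate",
        )
        assert ChainConfig.from_dict(cfg.to_dict()) == cfg

    @settings(derandomize=True, max_examples=50)
    @given(
        iterations=st.integers(2, 500),
        burn_frac=st.floats(0.0, 0.99),
        thin=st.integers(1, 7),
    )
    def test_kept_count_floor_formula(self, iterations, burn_frac, thin):
        burn_in = int(iterations * burn_frac)
        cfg = ChainConfig(iterations=iterations, burn_in=burn_in, thin=thin)
        assert cfg.kept == (iterations - burn_in) // thin


class TestInitialization:
    def test_identical_rows_fall_back_to_zeros(self):
        y = ResponseMatrix([[1, 0], [1, 0], [1, 0]])
        state = initialize_state(y, ChainConfig(iterations=10))
        assert np.all(state.theta.theta == 0.0)

    def test_item_start_is_unit_slope_zero_intercept(self):
        y = ResponseMatrix([[1, 0], [0, 1]])
        state = initialize_state(y, ChainConfig(iterations=10))
        assert np.all(state.items.alpha == 1.0)
        assert np.all(state.items.beta == 0.0)
        assert state.z is None and state.iteration == 0

    def test_sum_score_standardization(self):
        y = ResponseMatrix([[1, 1], [1, 0], [0, 0]])
        state = initialize_state(y, ChainConfig(iterations=10))
        assert state.theta.theta == pytest.approx([1.0, 0.0, -1.0])


class TestSerialChain:
    def test_gibbs_step_determinism_and_signs(self, small_dataset):
        y, _, _ = small_dataset
        cfg = ChainConfig(iterations=10, seed=0)
        state = initialize_state(y, cfg)
        s1 = gibbs_step(state, y, cfg, np.random.default_rng(9))
        s2 = gibbs_step(state, y, cfg, np.random.default_rng(9))
        assert np.array_equal(s1.theta.theta, s2.theta.theta)
        assert np.array_equal(s1.items.alpha, s2.items.alpha)
        s1.z.check_signs(y)
        assert s1.iteration == 1

    def test_bookkeeping_counts(self, small_dataset):
        y, _, _ = small_dataset
        s = run_chain(y, ChainConfig(iterations=10, burn_in=5, seed=0))
        assert s.kept == 5
        assert s.theta_draws.shape == (5, y.n)
        assert np.all(s.alpha_draws > 0)

    def test_same_seed_bit_identical(self, small_dataset):
        y, _, _ = small_dataset
        cfg = ChainConfig(iterations=20, burn_in=10, seed=11)
        assert run_chain(y, cfg).equals(run_chain(y, cfg))

    def test_abort_flags_partial_samples(self, small_dataset):
        y, _, _ = small_dataset
        cfg = ChainConfig(iterations=20, burn_in=0, seed=0, max_rejects=0)
        with pytest.raises(ChainAborted) as err:
            run_chain(y, cfg)
        assert err.value.partial is not None
        assert not err.value.partial.usable


class TestBlockedEquivalence:
    @pytest.mark.parametrize("shape", [(1, 1), (2, 2), (5, 5), (3, 7)])
    def test_serial_equivalent_mode_is_bit_identical(self, shape, small_dataset):
        y, _, _ = small_dataset
        base = ChainConfig(iterations=40, burn_in=20, seed=3, prior_mode="conjugate")
        serial = run_chain(y, base)
        grid = BlockGrid.from_shape(shape[0], shape[1], y.n, y.k)
        blocked = run_chain_blocked(
            y, replace(base, grid=grid, stream_mode="serial-equivalent")
        )
        assert blocked.equals(serial)

    def test_degenerate_grid_matches_manual_stream_replay(self, small_dataset):
        """A 1x1 per-block run equals plain serial updates fed the same streams."""
        y, _, _ = small_dataset
        cfg = ChainConfig(
            iterations=8,
            burn_in=0,
            seed=21,
            grid=BlockGrid.from_shape(1, 1, y.n, y.k),
            stream_mode="per-block",
        )
        blocked = run_chain_blocked(y, cfg)

        z_rng = _block_stream(21, _KERNEL_Z, 0, 0)
        t_rng = _block_stream(21, _KERNEL_THETA, 0, 0)
        i_rng = _block_stream(21, _KERNEL_ITEMS, 0, 0)
        state = initialize_state(y, cfg)
        theta, items = state.theta, state.items
        for it in range(cfg.iterations):
            z = update_Z(y, theta, items, z_rng)
            theta = sample_theta(theta_posterior_params(z, items, cfg.prior_mode), t_rng)
            items = update_items(z, theta, i_rng, cfg.max_rejects)
            assert np.array_equal(blocked.theta_draws[it], theta.theta)
            assert np.array_equal(blocked.alpha_draws[it], items.alpha)

    def test_per_block_grids_agree_statistically(self):
        """4x2 vs 2x4 per-block-stream chains give the same posterior means."""
        y, items, _ = simulate_responses(GeneratorSpec(n=200, k=16, seed=5))
        base = ChainConfig(iterations=1500, burn_in=500, seed=2, prior_mode="conjugate")
        runs = []
        for r, c in [(4, 2), (2, 4)]:
            grid = BlockGrid.from_shape(r, c, y.n, y.k)
            runs.append(
                run_chain_blocked(y, replace(base, grid=grid, stream_mode="per-block"))
            )
        a1 = runs[0].alpha_draws
        a2 = runs[1].alpha_draws
        for j in range(y.k):
            se = math.hypot(mcse(a1[:, j]), mcse(a2[:, j]))
            assert abs(a1[:, j].mean() - a2[:, j].mean()) < 4 * se

    def test_partial_sum_reduction_matches_single_pass(self, rng):
        x = rng.standard_normal(10_000)
        bounds = (0, 1000, 2500, 6000, 10_000)
        partials = [np.sum(x[a:b]) for a, b in zip(bounds, bounds[1:])]
        total = reduce_block_sums(partials)
        assert abs(total - np.sum(x)) <= 1e-10 * max(1.0, abs(np.sum(x)))

    def test_blocked_requires_grid(self, small_dataset):
        y, _, _ = small_dataset
        with pytest.raises(ValueError, match="BlockGrid"):
            run_chain_blocked(y, ChainConfig(iterations=5))


def _batch_se(x):
    return mcse(x)


class TestSubChainStationarity:
    """Exact-distribution checks on sub-chains whose posteriors are proper.

    Holding the item parameters fixed, the (Z, theta) sub-chain targets
    p(theta | y, xi), a well-behaved n-fold product of 1-D densities that
    direct quadrature evaluates.  Holding traits fixed with interlaced
    responses, the (Z, xi) sub-chain targets a proper 2-D item posterior.
    """

    def test_trait_subchain_matches_1d_quadrature(self, tiny_y, toy_items):
        y, items = tiny_y, toy_items
        iters, burn = 20_000, 2_000
        rng = np.random.default_rng(17)
        theta = TraitVector(np.zeros(y.n))
        draws = np.empty((iters, y.n))
        for it in range(iters):
            z = update_Z(y, theta, items, rng)
            theta = sample_theta(theta_posterior_params(z, items, "conjugate"), rng)
            draws[it] = theta.theta
        draws = draws[burn:]

        t = np.linspace(-6, 6, 4001)
        for i in range(y.n):
            like = np.ones_like(t)
            for j in range(items.k):
                p = ndtr(items.alpha[j] * t - items.beta[j])
                like *= p if y.values[i, j] == 1 else 1 - p
            dens = np.exp(-0.5 * t**2) * like
            w = dens / dens.sum()
            mean = np.sum(w * t)
            var = np.sum(w * (t - mean) ** 2)
            x = draws[:, i]
            assert abs(x.mean() - mean) < 3 * _batch_se(x)
            assert abs(x.var(ddof=1) - var) < 3 * _batch_se((x - x.mean()) ** 2)

    def test_item_subchain_matches_2d_quadrature(self):
        # responses broadly follow the traits but with an inversion, so the
        # item posterior is proper (no threshold separates the labels) and
        # concentrates at a moderate positive slope
        theta = TraitVector([-2.0, -1.5, -0.5, 0.5, 1.5, 2.0])
        yv = np.array([[0], [1], [0], [1], [0], [1]])
        y = ResponseMatrix(yv)
        items = ItemParameters([1.0], [0.0])
        iters, burn = 20_000, 2_000
        rng = np.random.default_rng(23)
        a_draws = np.empty(iters)
        b_draws = np.empty(iters)
        for it in range(iters):
            z = update_Z(y, theta, items, rng)
            items = update_items(z, theta, rng)
            a_draws[it] = items.alpha[0]
            b_draws[it] = items.beta[0]
        a_draws, b_draws = a_draws[burn:], b_draws[burn:]

        a = np.linspace(1e-3, 8, 500)
        b = np.linspace(-8, 8, 1000)
        A, B = np.meshgrid(a, b, indexing="ij")
        like = np.ones_like(A)
        for i in range(theta.n):
            p = ndtr(A * theta.theta[i] - B)
            like *= p if yv[i, 0] == 1 else 1 - p
        w = like / like.sum()
        ex_a, ex_b = np.sum(w * A), np.sum(w * B)
        assert abs(a_draws.mean() - ex_a) < 3 * _batch_se(a_draws)
        assert abs(b_draws.mean() - ex_b) < 3 * _batch_se(b_draws)


class TestParameterRecovery:
    def test_recovery_across_seeds(self):
        """Posterior means recover the generating slopes and intercepts.

        Five replications at n=1000, k=20 in conjugate mode: slope
        correlation at least 0.9 and intercept RMSE at most 0.15.
        """
        for seed in range(5):
            y, items, _ = simulate_responses(GeneratorSpec(n=1000, k=20, seed=100 + seed))
            s = run_chain(
                y,
                ChainConfig(
                    iterations=4000, burn_in=2000, seed=seed, prior_mode="conjugate"
                ),
            )
            alpha_hat = s.alpha_draws.mean(axis=0)
            beta_hat = s.beta_draws.mean(axis=0)
            corr = np.corrcoef(alpha_hat, items.alpha)[0, 1]
            rmse = math.sqrt(np.mean((beta_hat - items.beta) ** 2))
            assert corr >= 0.9, f"seed {seed}: slope correlation {corr:.3f}"
            assert rmse <= 0.15, f"seed {seed}: intercept RMSE {rmse:.3f}"
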