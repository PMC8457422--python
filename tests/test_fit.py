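"""Alternating algorithm: block updates, line search, convergence, multi-start."""

import numpy as np
import pytest
from scipy.optimize import minimize

from bintensor import (
    BinaryTensor,
    CPFactors,
    FitOptions,
    LinkSpec,
    cp_reconstruct,
    decompose,
    initialize_factors,
    line_search,
    log_likelihood,
    loss_frobenius,
    matched_logistic_link,
    multi_start_decompose,
    simulate_cp_threshold,
    update_block,
)

LOGISTIC = LinkSpec("logistic", 1.0)


def bernoulli_instance(dims, seed, p=0.5):
    rng = np.random.default_rng(seed)
    return BinaryTensor((rng.random(dims) < p).astype(np.int8))


class TestInitializeFactors:
    def test_deterministic_given_seed(self):
        a = initialize_factors((3, 4, 5), 2, seed=1)
        b = initialize_factors((3, 4, 5), 2, seed=1)
        for x, y in zip(a.factors, b.factors):
            np.testing.assert_array_equal(x, y)

    def test_leading_modes_unit_norm(self):
        fac = initialize_factors((3, 4, 5), 2, seed=2)
        for mat in fac.factors[:-1]:
            np.testing.assert_allclose(np.linalg.norm(mat, axis=0), 1.0, rtol=1e-12)

    def test_different_seeds_differ(self):
        a = initialize_factors((3, 4, 5), 2, seed=1)
        b = initialize_factors((3, 4, 5), 2, seed=2)
        assert any(
            not np.array_equal(x, y) for x, y in zip(a.factors, b.factors)
        )


class TestUpdateBlock:
    def test_full_mask_equals_no_mask(self):
        Y = bernoulli_instance((4, 4, 4), seed=3)
        fac = initialize_factors(Y.dims, 2, seed=0)
        no_mask = update_block(Y, fac, 1, LOGISTIC)
        full = update_block(Y, fac, 1, LOGISTIC, mask=np.ones(Y.dims, dtype=bool))
        np.testing.assert_array_equal(no_mask, full)

    def test_never_decreases_loglik(self):
        for seed in range(3):
            Y = bernoulli_instance((4, 5, 3), seed=seed)
            fac = initialize_factors(Y.dims, 2, seed=seed + 10)
            before = log_likelihood(Y, cp_reconstruct(fac), LOGISTIC)
            for mode in range(3):
                new = update_block(Y, fac, mode, LOGISTIC)
                fac = CPFactors(
                    [new if k == mode else f for k, f in enumerate(fac.factors)]
                )
                after = log_likelihood(Y, cp_reconstruct(fac), LOGISTIC)
                assert after >= before - 1e-9
                before = after

    def test_matches_generic_optimizer_over_block(self):
        """The block update maximizes L jointly over A_k (rows separate)."""
        sim = simulate_cp_threshold((4, 4, 4), 2, 0.5, seed=4)
        Y = sim.Y
        fac = initialize_factors(Y.dims, 2, seed=1)
        mode = 1
        ours = update_block(Y, fac, mode, LOGISTIC, max_iter=500, tol=1e-12)

        shape = fac.factors[mode].shape

        def neg_loglik(flat):
            mats = [f.copy() for f in fac.factors]
            mats[mode] = flat.reshape(shape)
            return -log_likelihood(Y, cp_reconstruct(CPFactors(mats)), LOGISTIC)

        oracle = minimize(
            neg_loglik, fac.factors[mode].ravel(), method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000},
        )
        assert np.linalg.norm(ours - oracle.x.reshape(shape)) < 1e-3


class TestLineSearch:
    def test_gamma_zero_when_new_point_best(self):
        sim = simulate_cp_threshold((5, 5, 5), 1, 0.3, seed=5)
        fac_prev = initialize_factors(sim.Y.dims, 1, seed=0)
        new = update_block(sim.Y, fac_prev, 0, LOGISTIC)
        fac_new = CPFactors([new, fac_prev.factors[1], fac_prev.factors[2]])
        gamma, blended, obj = line_search(fac_prev, fac_new, sim.Y, LOGISTIC)
        assert gamma == 0.0
        np.testing.assert_array_equal(blended.factors[0], new)

    def test_objective_beats_every_grid_point(self):
        Y = bernoulli_instance((4, 4, 4), seed=6)
        prev = initialize_factors(Y.dims, 2, seed=1)
        new = initialize_factors(Y.dims, 2, seed=2)
        gamma, _, obj = line_search(prev, new, Y, LOGISTIC, grid_size=21)
        for g in np.linspace(0, 1, 21):
            mats = [g * a + (1 - g) * b
                    for a, b in zip(prev.factors, new.factors)]
            val = log_likelihood(Y, cp_reconstruct(CPFactors(mats)), LOGISTIC)
            assert obj >= val - 1e-12

    def test_alpha_constraint_respected(self):
        Y = bernoulli_instance((3, 3, 3), seed=7)
        prev = initialize_factors(Y.dims, 1, seed=1)
        # previous iterate feasible under alpha; inflate the new point far out
        alpha = float(np.abs(cp_reconstruct(prev)).max()) * 1.5
        new = prev.copy()
        new.factors[-1] *= 100.0
        gamma, blended, _ = line_search(prev, new, Y, LOGISTIC, alpha=alpha)
        assert np.abs(cp_reconstruct(blended)).max() <= alpha + 1e-12


class TestDecompose:
    @pytest.mark.parametrize("family", ["logistic", "probit", "laplacian"])
    def test_trace_monotone_nondecreasing(self, family):
        sim = simulate_cp_threshold((8, 8, 8), 2, 0.3, seed=8)
        res = decompose(sim.Y, LinkSpec(family), FitOptions(rank=2, seed=3))
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_theta_hat_equals_reconstruction(self):
        sim = simulate_cp_threshold((6, 6, 6), 1, 0.3, seed=9)
        res = decompose(sim.Y, LOGISTIC, FitOptions(rank=1, seed=0))
        np.testing.assert_array_equal(res.theta_hat, cp_reconstruct(res.factors))

    def test_beats_zero_estimator_on_threshold_sim(self):
        sigma = 10**-0.5
        sim = simulate_cp_threshold((15, 15, 15), 1, sigma, seed=10)
        link = matched_logistic_link("gaussian", sigma)
        res = decompose(sim.Y, link, FitOptions(rank=1, seed=1))
        zero_loss = loss_frobenius(np.zeros(sim.Y.dims), sim.theta_true)
        assert loss_frobenius(res.theta_hat, sim.theta_true) < zero_loss

    def test_deterministic_given_seed(self):
        sim = simulate_cp_threshold((6, 6, 6), 2, 0.3, seed=11)
        a = decompose(sim.Y, LOGISTIC, FitOptions(rank=2, seed=5))
        b = decompose(sim.Y, LOGISTIC, FitOptions(rank=2, seed=5))
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
        assert a.loglik_trace == b.loglik_trace

    def test_rank_zero_is_probability_half_model(self):
        Y = bernoulli_instance((4, 4, 4), seed=12)
        res = decompose(Y, LOGISTIC, FitOptions(rank=0))
        np.testing.assert_array_equal(res.theta_hat, 0.0)
        assert res.objective == pytest.approx(64 * np.log(0.5))

    def test_coding_invariance(self):
        """Flipping the 0/1 coding negates theta-hat and keeps the objective."""
        sigma = 10**-0.5
        sim = simulate_cp_threshold((12, 12, 12), 2, sigma, seed=13)
        link = matched_logistic_link("gaussian", sigma)
        opts = FitOptions(rank=2, seed=4)
        res = decompose(sim.Y, link, opts)
        res_flip = decompose(BinaryTensor(1 - sim.Y.data), link, opts)
        assert abs(res.objective - res_flip.objective) <= 1e-6
        np.testing.assert_allclose(res_flip.theta_hat, -res.theta_hat, atol=1e-8)

    def test_finite_alpha_bounds_the_fit(self):
        """With a binding max-norm bound the returned reconstruction
        satisfies it and the trace stays monotone."""
        sim = simulate_cp_threshold((10, 10, 10), 1, 0.2, seed=21)
        free = decompose(sim.Y, LOGISTIC, FitOptions(rank=1, seed=2))
        alpha = 0.5 * float(np.abs(free.theta_hat).max())
        res = decompose(sim.Y, LOGISTIC, FitOptions(rank=1, seed=2, alpha=alpha))
        assert np.abs(res.theta_hat).max() <= alpha + 1e-9
        assert (np.diff(res.loglik_trace) >= -1e-9).all()

    def test_per_iteration_cost_roughly_linear_in_tensor_size(self):
        """Doubling every dimension (8x the entries) must not blow the sweep
        time up quadratically; the bound is deliberately loose because the
        small problem is overhead-dominated."""
        import time

        times = {}
        for d in (16, 32):
            sim = simulate_cp_threshold((d, d, d), 2, 0.3, seed=22)
            best = np.inf
            for _ in range(2):
                t0 = time.perf_counter()
                decompose(sim.Y, LOGISTIC, FitOptions(rank=2, seed=1, max_iter=2))
                best = min(best, time.perf_counter() - t0)
            times[d] = best
        assert times[32] < 40.0 * times[16]

    def test_missing_data_path_runs_and_is_monotone(self):
        rng = np.random.default_rng(14)
        sim = simulate_cp_threshold((8, 8, 8), 1, 0.3, seed=14)
        mask = rng.random(sim.Y.dims) < 0.8
        Y = BinaryTensor(sim.Y.data, mask)
        res = decompose(Y, LOGISTIC, FitOptions(rank=1, seed=2))
        assert (np.diff(res.loglik_trace) >= -1e-9).all()


class TestMultiStart:
    def test_single_start_identical_to_decompose(self):
        sim = simulate_cp_threshold((6, 6, 6), 1, 0.3, seed=15)
        single = decompose(sim.Y, LOGISTIC, FitOptions(rank=1, seed=3))
        multi = multi_start_decompose(sim.Y, LOGISTIC,
                                      FitOptions(rank=1, seed=3, n_starts=1))
        np.testing.assert_array_equal(single.theta_hat, multi.theta_hat)

    def test_deterministic(self):
        sim = simulate_cp_threshold((6, 6, 6), 1, 0.3, seed=16)
        opts = FitOptions(rank=1, seed=3, n_starts=3)
        a = multi_start_decompose(sim.Y, LOGISTIC, opts)
        b = multi_start_decompose(sim.Y, LOGISTIC, opts)
        assert a.start_objectives == b.start_objectives
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)

    def test_best_objective_nondecreasing_in_starts(self):
        sim = simulate_cp_threshold((8, 8, 8), 2, 0.3, seed=17)
        objectives = [
            multi_start_decompose(
                sim.Y, LOGISTIC, FitOptions(rank=2, seed=0, n_starts=n)
            ).objective
            for n in (1, 3, 5)
        ]
        assert objectives[0] <= objectives[1] + 1e-12
        assert objectives[1] <= objectives[2] + 1e-12
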