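import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeinf.inference import (
    DualState,
    Hyper,
    PrimalState,
    WeightEstimate,
    aggregate_runs,
    dual_coordinate_step,
    dual_neuinf,
    hinge_loss,
    neuinf,
    neuinf_epoch,
    parallel_solve,
    soft_threshold,
)
from conftest import make_block

NOBIAS = dict(fit_intercept=False)


def projected_gradient_dual(A, c, iters=500_000, kkt_tol=1e-11):
    """Independent maximizer of E(lam) = -c||A^T lam||^2 + sum(lam) over
    the box [0,1]^T: accelerated projected gradient (FISTA with adaptive
    restart) on the negated objective, stopped on the KKT residual."""
    T = A.shape[0]
    G = A @ A.T
    L = 2 * c * max(np.linalg.eigvalsh(G).max(), 1e-12)
    lam = np.zeros(T)
    z = lam.copy()
    tk = 1.0
    for it in range(iters):
        grad_z = 2.0 * c * (G @ z) - 1.0
        lam_new = np.clip(z - grad_z / L, 0.0, 1.0)
        tk_new = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        z = lam_new + (tk - 1.0) / tk_new * (lam_new - lam)
        if (lam_new - lam) @ grad_z > 0:  # adaptive restart
            z = lam_new
            tk_new = 1.0
        lam, tk = lam_new, tk_new
        if it % 500 == 0:
            g = 2.0 * c * (G @ lam) - 1.0
            kkt = np.where(lam <= 0, np.maximum(-g, 0),
                           np.where(lam >= 1, np.maximum(g, 0), np.abs(g)))
            if kkt.max() < kkt_tol:
                break
    u = A.T @ lam
    return lam, float(-c * u @ u + lam.sum())


class TestHingeLoss:
    @pytest.mark.parametrize("x,expected", [(0, 1), (1, 0), (-1, 2),
                                            (100, 0)])
    def test_standard_values(self, x, expected):
        assert hinge_loss(x) == expected

    def test_modified_hinge_goes_negative(self):
        assert np.isclose(hinge_loss(2.0, eps=0.1), -0.1)

    def test_eps_out_of_range(self):
        with pytest.raises(ValueError):
            hinge_loss(0.0, eps=1.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_decreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert hinge_loss(lo) >= hinge_loss(hi)
        assert hinge_loss(lo, eps=0.3) >= hinge_loss(hi, eps=0.3)


class TestSoftThreshold:
    @pytest.mark.parametrize("x,eta,expected", [(5, 2, 3), (-5, 2, -3),
                                                (1, 2, 0), (7.5, 0, 7.5)])
    def test_piecewise_cases(self, x, eta, expected):
        assert soft_threshold(x, eta) == expected

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-1e6, 1e6), st.floats(0, 1e3))
    def test_shrinkage_never_grows(self, x, eta):
        assert abs(soft_threshold(x, eta)) <= abs(x)

    def test_vectorized(self):
        out = soft_threshold(np.array([5.0, -5.0, 1.0]), 2.0)
        assert np.array_equal(out, [3.0, -3.0, 0.0])


class TestNeuinfEpoch:
    def test_update_and_thresholding_hand_example(self):
        # margin 0 -> L=1 -> w = gamma * A row; then eta=0.15 zeroes it
        K = np.array([[1.0, 1.0]])
        y = np.array([1], dtype=np.int8)
        block = make_block(K, y)  # A = (1, 1)
        h = Hyper(algo="neuinf", gamma=0.1, eta=0.0, **NOBIAS)
        state = neuinf_epoch(PrimalState(w=np.zeros(2)), block, h)
        assert np.allclose(state.w, [0.1, 0.1])
        assert state.tau == 1
        h2 = Hyper(algo="neuinf", gamma=0.1, eta=0.15, **NOBIAS)
        state2 = neuinf_epoch(PrimalState(w=np.zeros(2)), block, h2)
        assert np.array_equal(state2.w, [0.0, 0.0])

    def test_satisfied_row_leaves_w_unchanged(self):
        block = make_block(np.array([[1.0, 0.0]]), np.array([1]))
        h = Hyper(algo="neuinf", gamma=0.1, eta=0.0, **NOBIAS)
        state = neuinf_epoch(PrimalState(w=np.array([2.0, 0.0])), block, h)
        assert np.array_equal(state.w, [2.0, 0.0])
        assert state.tau == 0

    def test_divergence_raises_with_advice(self):
        # irreconcilable rows with a huge step: w ping-pongs and blows up
        block = make_block(np.array([[1.0, 2.0], [1.0, 2.0]]),
                           np.array([1, -1]))
        h = Hyper(algo="neuinf", gamma=100.0, eta=0.0, epochs=300, **NOBIAS)
        with pytest.raises(FloatingPointError, match="gamma"):
            neuinf([block], h)


class TestDualCoordinateStep:
    def test_hand_derived_single_row(self):
        # T=1, A=(1,0), c=0.5: optimum clipped at 1, E = -0.5 + 1 = 0.5
        block = make_block(np.array([[1.0, 0.0]]), np.array([1]))
        state = DualState(lam=np.zeros(1), u=np.zeros(2), c=0.5)
        dual_coordinate_step(state, 0, block)
        assert state.lam[0] == 1.0
        assert np.array_equal(state.u, [1.0, 0.0])
        assert np.isclose(state.objective, 0.5)

    def test_fixed_point_no_change(self):
        block = make_block(np.array([[2.0, 0.0]]), np.array([1]))
        # optimum: lam = 1/(2c*4) = 0.125 at c=1
        state = DualState(lam=np.array([0.125]), u=np.array([0.25, 0.0]),
                          c=1.0)
        dual_coordinate_step(state, 0, block)
        assert np.isclose(state.lam[0], 0.125)

    def test_objective_never_decreases(self, random_instance):
        block = random_instance(seed=5)
        state = DualState(lam=np.zeros(block.n_rows), u=np.zeros(block.n),
                          c=1.0)
        rng = np.random.default_rng(0)
        prev = state.objective
        for t in rng.integers(0, block.n_rows, size=200):
            dual_coordinate_step(state, int(t), block)
            cur = state.objective
            assert cur >= prev - 1e-12
            prev = cur


class TestDualNeuinf:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_projected_gradient_oracle(self, random_instance, seed):
        block = random_instance(T=40, n=8, seed=seed)
        c = 1.0
        est = dual_neuinf([block], Hyper(algo="dual", c=c, epochs=30_000,
                                         eta=0.0, seed=seed, **NOBIAS),
                          return_state=True)
        _, E_star = projected_gradient_dual(block.A, c)
        assert abs(est.objective - E_star) <= 1e-6

    def test_dual_feasibility_and_u_identity(self, random_instance):
        block = random_instance(T=60, n=6, seed=11)
        est = dual_neuinf([block], Hyper(algo="dual", epochs=20, eta=0.0,
                                         seed=1, **NOBIAS), return_state=True)
        lam = est.state.lam
        assert np.all(lam >= 0) and np.all(lam <= 1)
        assert np.allclose(est.state.u, block.A.T @ lam, atol=1e-9)

    def test_objective_monotone_across_sweeps(self, random_instance):
        block = random_instance(T=80, n=5, seed=2)
        est = dual_neuinf([block], Hyper(algo="dual", epochs=30, eta=0.0,
                                         seed=4, **NOBIAS))
        traj = np.array(est.objective_trajectory)
        assert np.all(np.diff(traj) >= -1e-9)

    def test_w_equals_At_lambda_before_thresholding(self, random_instance):
        block = random_instance(seed=3)
        est = dual_neuinf([block], Hyper(algo="dual", epochs=10, eta=0.5,
                                         seed=0, **NOBIAS), return_state=True)
        assert np.allclose(est.w_raw, block.A.T @ est.state.lam, atol=1e-9)
        assert np.array_equal(est.w, soft_threshold(est.w_raw, 0.5))

    def test_all_zero_A_degenerate(self):
        block = make_block(np.zeros((7, 3)), np.ones(7, dtype=np.int8))
        est = dual_neuinf([block], Hyper(algo="dual", epochs=2, eta=0.0,
                                         **NOBIAS), return_state=True)
        assert np.array_equal(est.w, np.zeros(3))
        assert np.all(est.state.lam == 1.0)  # E = sum(lam) maximized at 1
        assert np.isclose(est.objective, 7.0)


class TestParallelSolve:
    def test_dual_m1_reduces_to_sequential(self, random_instance):
        block = random_instance(seed=21)
        h = Hyper(algo="parallel-dual", M=1, epochs=7, eta=0.0, seed=9,
                  **NOBIAS)
        a = parallel_solve([block], h)
        b = dual_neuinf([block], Hyper(algo="dual", M=1, epochs=7, eta=0.0,
                                       seed=9, **NOBIAS))
        assert np.array_equal(a.w, b.w)
        assert a.objective == b.objective

    def test_primal_m1_w1_reduces_to_sequential(self, random_instance):
        block = random_instance(seed=22)
        h = Hyper(algo="parallel-neuinf", M=1, workers=1, epochs=3,
                  gamma=0.05, eta=0.01, seed=9, **NOBIAS)
        a = parallel_solve([block], h)
        b = neuinf([block], Hyper(algo="neuinf", epochs=3, gamma=0.05,
                                  eta=0.01, seed=9, **NOBIAS))
        assert np.array_equal(a.w, b.w)

    def test_cocoa_m4_objective_near_m1_optimum(self, random_instance):
        block = random_instance(T=40, n=8, seed=30)
        quarters = [make_block(block.Kp[i:i + 10], block.y[i:i + 10])
                    for i in range(0, 40, 10)]
        h = Hyper(algo="parallel-dual", M=4, epochs=3000, eta=0.0, seed=2,
                  **NOBIAS)
        est4 = parallel_solve(quarters, h)
        est1 = dual_neuinf([block], Hyper(algo="dual", epochs=800, eta=0.0,
                                          tol=1e-15, seed=2, **NOBIAS))
        assert abs(est4.objective - est1.objective) <= 1e-4

    def test_workers_sharding_is_deterministic(self, random_instance):
        block = random_instance(seed=40)
        h = Hyper(algo="parallel-neuinf", M=1, workers=3, epochs=2, seed=5,
                  **NOBIAS)
        a = parallel_solve([block], h)
        b = parallel_solve([block], h)
        assert np.array_equal(a.w, b.w)


class TestAggregateRuns:
    def test_idempotent_and_symmetric(self):
        w = np.array([1.0, -2.0, 0.5])
        e = WeightEstimate(target=0, w=w, algo="dual")
        assert np.array_equal(aggregate_runs([e, e]).w, w)
        e2 = WeightEstimate(target=0, w=-w, algo="dual")
        assert np.array_equal(aggregate_runs([e, e2]).w, np.zeros(3))

    def test_mean_of_five_runs(self, rng):
        ws = [rng.normal(size=4) for _ in range(5)]
        ests = [WeightEstimate(target=1, w=w, algo="dual") for w in ws]
        agg = aggregate_runs(ests)
        assert np.allclose(agg.w, np.mean(ws, axis=0))
        assert agg.n_runs == 5

    def test_mismatched_lengths_rejected(self):
        a = WeightEstimate(target=0, w=np.zeros(3), algo="dual")
        b = WeightEstimate(target=0, w=np.zeros(4), algo="dual")
        with pytest.raises(ValueError):
            aggregate_runs([a, b])
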