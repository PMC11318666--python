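"""Optimizer unit tests: error vectors, resultants, fixed points, convergence."""
import numpy as np
import pytest

from evrc import coclustering, evaluate, reconstruct as rec, simulate
from evrc.errors import ParameterError, ValidationError
from evrc.coclustering import CoCCMatrix
from evrc.matrices_io import DistanceMatrix, freq_to_dist
from evrc.reconstruct import OptimizerConfig, Structure


def dist_matrix(D):
    D = np.asarray(D, dtype=float)
    np.fill_diagonal(D, np.inf)
    return DistanceMatrix(D=D, alpha_used=1.0)


def full_weights(n):
    W = np.ones((n, n))
    np.fill_diagonal(W, 0.0)
    return CoCCMatrix(values=W)


def resultant_brute(P, D, W, beta, j):
    """Term-by-term recomputation of the weighted-average resultant."""
    N = len(P)
    total = np.zeros(3)
    wsum = 0.0
    for i in range(N):
        if i == j or not np.isfinite(D[j, i]):
            continue
        diff = P[i] - P[j]
        d = np.linalg.norm(diff)
        total += W[j, i] * (diff / d) * (d - D[j, i])
        wsum += W[j, i]
    if wsum == 0.0:
        return np.zeros(3)
    return total / (wsum * (N - 1) ** beta)


class TestInitCoords:
    def test_seed_determinism(self):
        D = dist_matrix(np.ones((5, 5)))
        cfg = OptimizerConfig(seed=7)
        a = rec.init_coords(5, cfg, D)
        b = rec.init_coords(5, cfg, D)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self):
        D = dist_matrix(np.ones((5, 5)))
        a = rec.init_coords(5, OptimizerConfig(seed=1), D)
        b = rec.init_coords(5, OptimizerConfig(seed=2), D)
        assert not np.allclose(a.coords, b.coords)

    def test_two_points_distinct(self):
        D = dist_matrix(np.ones((2, 2)))
        for seed in range(5):
            S = rec.init_coords(2, OptimizerConfig(seed=seed), D)
            assert np.linalg.norm(S.coords[0] - S.coords[1]) > 1e-12

    def test_too_few_bins(self):
        D = dist_matrix(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            rec.init_coords(1, OptimizerConfig(), D)

    def test_scale_follows_mean_distance(self):
        big = dist_matrix(np.full((20, 20), 100.0))
        S = rec.init_coords(20, OptimizerConfig(seed=0), big)
        assert S.coords.max() > 10.0


class TestErrorVector:
    def test_too_far_pulls_together(self):
        v = rec.error_vector(np.array([2.0, 0, 0]), np.zeros(3), 1.0)
        np.testing.assert_allclose(v, [1.0, 0, 0])

    def test_satisfied_constraint_is_zero(self):
        v = rec.error_vector(np.array([0, 3.0, 0]), np.zeros(3), 3.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_too_close_pushes_apart(self):
        # j sits 3 away but should be 5 away: the vector moves j further out
        v = rec.error_vector(np.zeros(3), np.array([0, 0, 3.0]), 5.0)
        np.testing.assert_allclose(v, [0, 0, 2.0])

    def test_coincident_guard_magnitude_and_determinism(self):
        p = np.zeros(3)
        v1 = rec.error_vector(p, p, 4.0, rng=np.random.default_rng(5))
        v2 = rec.error_vector(p, p, 4.0, rng=np.random.default_rng(5))
        assert np.linalg.norm(v1) == pytest.approx(4.0)
        np.testing.assert_array_equal(v1, v2)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            rec.error_vector(np.zeros(3), np.ones(3), np.inf)


class TestResultantAndObjective:
    def test_satisfied_structure_has_zero_resultants(self, rng):
        P = rng.normal(size=(6, 3))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        S = Structure(coords=P)
        Dm, W = dist_matrix(D), full_weights(6)
        for j in range(6):
            np.testing.assert_allclose(rec.resultant(j, S, Dm, W, 0.1), 0.0, atol=1e-12)
        assert rec.objective(S, Dm, W, 0.1) == pytest.approx(0.0, abs=1e-10)

    def test_two_bin_weight_cancels(self, rng):
        # with one constraint the weighted average equals the bare error vector
        P = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        S = Structure(coords=P)
        Dm = dist_matrix([[0, 1.0], [1.0, 0]])
        for c in (0.2, 1.0):
            W = CoCCMatrix(values=np.array([[0, c], [c, 0.0]]))
            E1 = rec.resultant(1, S, Dm, W, beta=0.0)
            np.testing.assert_allclose(E1, rec.error_vector(P[0], P[1], 1.0))

    @pytest.mark.parametrize("beta", [0.0, 0.1, 1.0])
    def test_matches_brute_force(self, rng, beta):
        n = 10
        P = rng.normal(size=(n, 3))
        D = np.abs(rng.normal(2.0, 0.3, size=(n, n)))
        D = (D + D.T) / 2
        D[rng.random((n, n)) < 0.2] = np.inf
        D = np.where(np.isinf(D) | np.isinf(D.T), np.inf, D)
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        Dm = dist_matrix(D)
        Wm = CoCCMatrix(values=W)
        S = Structure(coords=P)
        for j in range(n):
            expected = resultant_brute(P, Dm.D, W, beta, j)
            np.testing.assert_allclose(rec.resultant(j, S, Dm, Wm, beta), expected, atol=1e-12)
        # objective equals the sum of brute-force resultant norms
        F = sum(np.linalg.norm(resultant_brute(P, Dm.D, W, beta, j)) for j in range(n))
        assert rec.objective(S, Dm, Wm, beta) == pytest.approx(F, rel=1e-12)


class TestStep:
    def test_fixed_point_unchanged(self, rng):
        P = rng.normal(size=(5, 3))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        S = Structure(coords=P)
        S2, F = rec.step(S, dist_matrix(D), full_weights(5), 0.1)
        assert F == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(S2.coords, P, atol=1e-12)

    def test_synchronous_two_bin_overshoot(self):
        # both bins move a full unit toward each other and swap through the
        # midpoint: the documented synchronous-update overshoot at tiny N
        P = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        Dm = dist_matrix([[0, 1.0], [1.0, 0]])
        S2, F = rec.step(Structure(coords=P), Dm, full_weights(2), beta=0.0)
        assert F == pytest.approx(2.0)
        np.testing.assert_allclose(S2.coords, [[1.0, 0, 0], [1.0, 0, 0]], atol=1e-12)

    def test_determinism(self, rng):
        P = rng.normal(size=(8, 3))
        D = np.abs(rng.normal(2, 0.2, size=(8, 8)))
        D = (D + D.T) / 2
        Dm, W = dist_matrix(D), full_weights(8)
        S = Structure(coords=P.copy())
        a, Fa = rec.step(S, Dm, W, 0.1)
        b, Fb = rec.step(S, Dm, W, 0.1)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert Fa == Fb

    def test_rigid_motion_equivariance(self, rng):
        """Rotating/translating before a step equals transforming after it."""
        from scipy.spatial.transform import Rotation

        n = 12
        P = rng.normal(size=(n, 3))
        D = np.abs(rng.normal(2, 0.3, size=(n, n)))
        D = (D + D.T) / 2
        Dm, W = dist_matrix(D), full_weights(n)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        stepped, _ = rec.step(Structure(coords=P), Dm, W, 0.1)
        transformed_then_stepped, _ = rec.step(Structure(coords=P @ R.T + t), Dm, W, 0.1)
        np.testing.assert_allclose(
            transformed_then_stepped.coords, stepped.coords @ R.T + t, atol=1e-9
        )


class TestRun:
    def _circle_problem(self, n=60):
        S0 = simulate.generate_model(simulate.ModelSpec("circle", n_points=n))
        C = simulate.contacts_from_structure(S0)
        D = freq_to_dist(C, alpha=1.0)
        W = coclustering.cocc_matrix(coclustering.build_graph(D))
        return S0, D, W

    def test_noiseless_circle_recovers_shape(self):
        S0, D, W = self._circle_problem()
        S, trace = rec.run(D, W, OptimizerConfig(alpha=1.0, seed=0))
        assert trace.converged
        assert evaluate.distance_pcc(S0, S) > 0.999

    def test_single_iteration_cap(self):
        _, D, W = self._circle_problem(20)
        S, trace = rec.run(D, W, OptimizerConfig(seed=0, max_iter=1))
        assert trace.iterations_run == 1
        assert not trace.converged

    def test_trace_descends_to_near_zero(self):
        _, D, W = self._circle_problem()
        _, trace = rec.run(D, W, OptimizerConfig(alpha=1.0, seed=3))
        F = trace.F_values
        assert len(F) == trace.iterations_run
        assert F[0] > 10 * F[-1]
        assert trace.final_dF < 1e-6

    def test_bit_identical_traces_for_same_seed(self):
        _, D, W = self._circle_problem(30)
        _, t1 = rec.run(D, W, OptimizerConfig(seed=11))
        _, t2 = rec.run(D, W, OptimizerConfig(seed=11))
        np.testing.assert_array_equal(t1.F_values, t2.F_values)

    def test_size_mismatch(self):
        _, D, W = self._circle_problem(20)
        with pytest.raises(ValidationError):
            rec.run(dist_matrix(np.ones((5, 5))), W, OptimizerConfig())


class TestSmooth:
    def test_auto_is_identity(self, rng):
        S = Structure(coords=rng.normal(size=(10, 3)))
        np.testing.assert_array_equal(rec.smooth(S, "auto").coords, S.coords)

    def test_straight_line_interior_invariant(self):
        t = np.arange(30, dtype=float)
        S = Structure(coords=np.column_stack([t, 2 * t, -t]))
        sm = rec.smooth(S, sigma=2.0)
        np.testing.assert_allclose(sm.coords[8:-8], S.coords[8:-8], atol=1e-8)

    def test_chains_filtered_independently(self, rng):
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        chains = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        both = rec.smooth(Structure(coords=np.vstack([a, b]), chains=chains), 2.0)
        alone = rec.smooth(Structure(coords=a), 2.0)
        np.testing.assert_allclose(both.coords[:15], alone.coords, atol=1e-12)

    @pytest.mark.parametrize("sigma", [0.0, -1.0, "bogus"])
    def test_bad_sigma(self, sigma, rng):
        S = Structure(coords=rng.normal(size=(5, 3)))
        with pytest.raises(ParameterError):
            rec.smooth(S, sigma)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"beta": -0.5},
            {"tol": 0.0},
            {"max_iter": 0},
            {"init_scale": 0.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ParameterError):
            OptimizerConfig(**kwargs)
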