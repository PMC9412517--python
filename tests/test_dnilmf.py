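import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodnilmf.data_io import InteractionMatrix, SimilarityMatrix
from rodnilmf.dnilmf import (
    DiffusedKernel,
    DnilmfConfig,
    LatentFactors,
    build_diffused_kernels,
    diffuse,
    fit_dnilmf,
    fit_latent_factors,
    gaussian_kernel_matrix,
    infer_new_latents,
    infer_profile,
    local_similarity,
    predict_interactions,
    similarity_to_kernel,
    status_matrix,
)
from rodnilmf.dnilmf import _objective, _smoothed_logits
from scipy.special import expit


def _sim(values):
    n = len(values)
    return SimilarityMatrix(np.asarray(values, float), tuple(f"e{i}" for i in range(n)))


class TestInferProfile:
    def test_single_neighbor_normalization_cancels(self):
        Y = np.array([[0, 0, 0], [1, 0, 1]])
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        np.testing.assert_allclose(infer_profile(Y, S, 0, K=1), [1, 0, 1])

    def test_equal_weights_average(self):
        Y = np.array([[0, 0], [1, 0], [0, 1]])
        S = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.0], [0.4, 0.0, 1.0]])
        np.testing.assert_allclose(infer_profile(Y, S, 0, K=2), [0.5, 0.5])

    def test_hand_weighted_average(self):
        Y = np.array([[0, 0], [1, 0], [0, 1]])
        S = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.0], [0.2, 0.0, 1.0]])
        np.testing.assert_allclose(infer_profile(Y, S, 0, K=2), [0.8, 0.2])

    def test_errors_without_known_neighbors(self):
        Y = np.zeros((2, 3))
        S = np.eye(2)
        with pytest.raises(ValueError, match="no known"):
            infer_profile(Y, S, 0, K=1)

    def test_zero_similarity_neighbors_error(self):
        Y = np.array([[0, 0], [1, 1]])
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero similarity"):
            infer_profile(Y, S, 0, K=1)

    def test_target_side_uses_columns(self):
        Y = np.array([[1, 0], [0, 0], [1, 0]])
        S = np.array([[1.0, 0.9], [0.9, 1.0]])
        np.testing.assert_allclose(infer_profile(Y, S, 1, K=1, side="target"), [1, 0, 1])


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        K = gaussian_kernel_matrix(np.array([[1.0, 0.0], [1.0, 0.0]]), phi=1.0)
        np.testing.assert_allclose(K, 1.0)

    def test_hand_computed_value(self):
        K = gaussian_kernel_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]), phi=2.0)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_kernel_is_psd(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((10, 6))
        K = gaussian_kernel_matrix(P, phi=1.3)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_depends_only_on_distances(self):
        rng = np.random.default_rng(0)
        P = rng.random((8, 5))
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            gaussian_kernel_matrix(P, 1.0), gaussian_kernel_matrix(P[:, perm], 1.0)
        )


class TestSimilarityToKernel:
    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(1)
        B = rng.random((6, 4))
        A = B @ B.T
        A = A / np.sqrt(np.outer(np.diag(A), np.diag(A)))
        np.fill_diagonal(A, 1.0)
        np.testing.assert_allclose(similarity_to_kernel(A), A, atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_output_psd_and_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        K = similarity_to_kernel(A)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-8)


class TestStatusMatrix:
    def test_hand_2x2(self):
        P = status_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        np.testing.assert_allclose(np.diag(P), 0.5)
        np.testing.assert_allclose(P[0, 1], 0.5)  # 0.5 / (2 * 0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.random((7, 7)) + 0.1
        K = (K + K.T) / 2
        np.testing.assert_allclose(status_matrix(K).sum(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        K = rng.random((5, 5)) + 0.1
        K = (K + K.T) / 2
        np.testing.assert_allclose(status_matrix(K), status_matrix(7.3 * K), atol=1e-12)

    def test_zero_row_errors(self):
        K = np.eye(3)
        with pytest.raises(ValueError, match="off-diagonal"):
            status_matrix(K)


class TestLocalSimilarity:
    def test_full_neighborhood_row_normalizes_off_diagonal(self):
        rng = np.random.default_rng(3)
        P = rng.random((5, 5))
        L = local_similarity(P, K=4)
        off = P.copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(L, off / off.sum(axis=1, keepdims=True))

    def test_k1_single_unit_entry_per_row(self):
        rng = np.random.default_rng(4)
        P = rng.random((6, 6))
        L = local_similarity(P, K=1)
        assert ((L == 1).sum(axis=1) == 1).all() and np.allclose(L.sum(axis=1), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((8, 8)) + 0.01
        K = int(rng.integers(1, 7))
        np.testing.assert_allclose(local_similarity(P, K).sum(axis=1), 1.0, atol=1e-12)


class TestDiffuse:
    def _status(self, seed, n=6):
        rng = np.random.default_rng(seed)
        K = rng.random((n, n)) + 0.05
        return status_matrix((K + K.T) / 2)

    def test_equal_inputs_stay_equal(self):
        P = self._status(0)
        out = diffuse(P, P.copy(), K=3, t=4)
        L = local_similarity(P, 3)
        ref = P.copy()
        for _ in range(4):
            ref = L @ ref @ L.T + np.eye(len(P))
        np.testing.assert_allclose(out.values, (ref + ref.T) / 2, atol=1e-10)

    def test_output_symmetric(self):
        out = diffuse(self._status(1), self._status(2), K=3, t=5)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-8)

    def test_hand_t1_3x3(self):
        P1 = self._status(3, n=3)
        P2 = self._status(4, n=3)
        L1 = local_similarity(P1, 2)
        L2 = local_similarity(P2, 2)
        I = np.eye(3)
        expected = ((L1 @ P2 @ L1.T + I) + (L2 @ P1 @ L2.T + I)) / 2
        expected = (expected + expected.T) / 2
        out = diffuse(P1, P2, K=2, t=1)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_long_runs_stay_finite_and_symmetric(self):
        out = diffuse(self._status(5, 20), self._status(6, 20), K=5, t=50)
        assert np.all(np.isfinite(out.values))
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-8)


class TestFit:
    def _kernels(self, M, N, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.random((M, M)) * 0.2
        B = rng.random((N, N)) * 0.2
        Kd = (A + A.T) / 2 + np.eye(M)
        Kt = (B + B.T) / 2 + np.eye(N)
        return DiffusedKernel(Kd, "drug"), DiffusedKernel(Kt, "target")

    def test_objective_non_decreasing(self):
        rng = np.random.default_rng(7)
        M, N = 12, 10
        Y = (rng.random((M, N)) < 0.3).astype(float)
        Sd, St = self._kernels(M, N)
        cfg = DnilmfConfig(rank=4, iterations=40, seed=1)
        # re-run the ascent loop manually to observe the objective
        objs = []
        from rodnilmf import dnilmf as mod

        orig = mod._objective

        def spy(*args, **kw):
            v = orig(*args, **kw)
            objs.append(v)
            return v

        mod._objective = spy
        try:
            fit_latent_factors(Y, Sd, St, cfg)
        finally:
            mod._objective = orig
        accepted = [objs[0]]
        for v in objs[1:]:
            if v >= accepted[-1] - 1e-12:
                accepted.append(v)
        # the accepted sequence is the fit's trajectory: never decreasing
        assert all(b >= a - 1e-9 for a, b in zip(accepted, accepted[1:]))
        assert accepted[-1] > accepted[0]

    def test_all_zero_matrix_predicts_below_half(self):
        M, N = 8, 6
        Y = np.zeros((M, N))
        Sd, St = self._kernels(M, N, seed=2)
        cfg = DnilmfConfig(rank=3, positive_weight=1.0, iterations=60, seed=2)
        f = fit_latent_factors(Y, Sd, St, cfg)
        P = predict_interactions(f, Sd, St, cfg.alpha, cfg.rho, cfg.tau)
        assert (P < 0.5).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        Y = (rng.random((10, 9)) < 0.3).astype(float)
        Sd, St = self._kernels(10, 9, seed=3)
        cfg = DnilmfConfig(rank=3, iterations=25, seed=5)
        a = fit_latent_factors(Y, Sd, St, cfg)
        b = fit_latent_factors(Y, Sd, St, cfg)
        np.testing.assert_array_equal(a.drug_factors, b.drug_factors)
        np.testing.assert_array_equal(a.target_factors, b.target_factors)


class TestInferNewLatents:
    def test_single_known_neighbor_copies_row(self):
        f = LatentFactors(np.arange(6.0).reshape(3, 2), np.zeros((4, 2)))
        S = np.array([[1, 0.9, 0.0], [0.9, 1, 0], [0.0, 0, 1.0]])
        known = np.array([False, True, True])
        out = infer_new_latents(f, S, known, K=1)
        np.testing.assert_allclose(out.drug_factors[0], f.drug_factors[1])

    def test_equal_neighbors_average(self):
        f = LatentFactors(np.array([[0.0, 0], [2, 0], [0, 2]]), np.zeros((4, 2)))
        S = np.array([[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1.0]])
        known = np.array([False, True, True])
        out = infer_new_latents(f, S, known, K=2)
        np.testing.assert_allclose(out.drug_factors[0], [1.0, 1.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(size=(8, 3))
        f = LatentFactors(rows.copy(), np.zeros((5, 3)))
        S = rng.random((8, 8))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        known = np.array([True] * 5 + [False] * 3)
        K = 3
        out = infer_new_latents(f, S, known, K)
        for i in (5, 6, 7):
            sims = [(S[i, u], u) for u in range(5)]
            top = sorted(sims, key=lambda x: (-x[0], x[1]))[:K]
            w = np.array([s for s, _ in top])
            nb = np.array([rows[u] for _, u in top])
            np.testing.assert_allclose(out.drug_factors[i], w @ nb / w.sum())


class TestPredict:
    def test_zero_factors_give_half(self):
        f = LatentFactors(np.zeros((3, 2)), np.zeros((4, 2)))
        P = predict_interactions(f, np.eye(3), np.eye(4), 0.5, 0.25, 0.25)
        np.testing.assert_allclose(P, 0.5)

    def test_hand_computed_sigmoid(self):
        f = LatentFactors(np.array([[1.0]]), np.array([[1.0]]))
        P = predict_interactions(f, np.eye(1), np.eye(1), 1.0, 0.0, 0.0)
        assert P[0, 0] == pytest.approx(expit(1.0))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        D = rng.normal(size=(6, 3))
        T = rng.normal(size=(5, 3))
        Sd = rng.random((6, 6))
        Sd = (Sd + Sd.T) / 2
        St = rng.random((5, 5))
        St = (St + St.T) / 2
        P = predict_interactions(LatentFactors(D, T), Sd, St, 0.5, 0.25, 0.25)
        perm = rng.permutation(6)
        P2 = predict_interactions(
            LatentFactors(D[perm], T), Sd[np.ix_(perm, perm)], St, 0.5, 0.25, 0.25
        )
        np.testing.assert_allclose(P2, P[perm], atol=1e-12)

    def test_coefficients_must_sum_to_one(self):
        f = LatentFactors(np.zeros((2, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="sum to 1"):
            predict_interactions(f, np.eye(2), np.eye(2), 0.5, 0.3, 0.3)


class TestEndToEnd:
    def test_probabilities_in_unit_interval_over_parameter_grid(self, small_network):
        Y = small_network["Y"]
        for alpha, rho, tau in [(1.0, 0.0, 0.0), (0.5, 0.25, 0.25), (0.9, 0.05, 0.05)]:
            for K in (5, 10):
                cfg = DnilmfConfig(alpha=alpha, rho=rho, tau=tau, neighbors=K,
                                   rank=5, iterations=30, seed=0)
                model = fit_dnilmf(Y, small_network["drug_sim"],
                                   small_network["target_sim"], cfg)
                P = model.predict()
                assert np.all((P > 0) & (P < 1))

    def test_config_validates_coefficients(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DnilmfConfig(alpha=0.9, rho=0.2, tau=0.2)
        with pytest.warns(UserWarning, match="outside the usual"):
            DnilmfConfig(alpha=0.4, rho=0.35, tau=0.25)
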