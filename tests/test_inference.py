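"""Variational updates against stationarity, formula and sampling oracles.

Each Gaussian update must place its mean at a stationary point of the
expected surrogate objective (checked by central finite differences and, for
the smallest instance, by an independent numerical optimizer); the Gamma and
local-parameter updates must match independent re-evaluations of their
moment formulas or Monte-Carlo estimates over posterior draws.
"""

import numpy as np
import pytest

from conftest import make_instance, randomized_state
from logitcp.inference import (
    ModelConfig,
    compute_AB,
    initialize_state,
    predict,
    surrogate_objective,
    update_G,
    update_H,
    update_lambda,
    update_sigma,
    update_U,
    update_V,
    update_W,
    update_xi,
)
from logitcp.tensorops import (
    cp_reconstruct,
    generalized_inner_product,
    lambda_xi,
    sigmoid,
)


class TestInitialization:
    def test_same_seed_bit_identical(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        s1 = initialize_state(Y, Sm, Sd, cfg)
        s2 = initialize_state(Y, Sm, Sd, cfg)
        np.testing.assert_array_equal(s1.G.mean, s2.G.mean)
        np.testing.assert_array_equal(s1.U.mean, s2.U.mean)

    def test_xi_all_ones_and_identity_covariances(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        s = initialize_state(Y, Sm, Sd, cfg)
        np.testing.assert_array_equal(s.xi, 1.0)
        I, J, K = Y.shape
        np.testing.assert_array_equal(s.G.row_cov, np.tile(np.eye(cfg.R), (I, 1, 1)))
        np.testing.assert_array_equal(s.U.col_cov, np.tile(np.eye(I), (cfg.R, 1, 1)))

    def test_misaligned_registry_rejected(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        from logitcp.similarity import SimilarityMatrix

        bad = SimilarityMatrix(Sm.values, ["x" + m for m in Sm.entity_ids])
        with pytest.raises(ValueError, match="misaligned"):
            initialize_state(Y, bad, Sd, cfg)


class TestComputeAB:
    def test_zero_entry_plugin(self, tiny_instance):
        Y, *_ = tiny_instance
        Y = Y.copy()
        Y.values[:] = 0
        xi = np.full(Y.shape, 0.7)
        A, B = compute_AB(Y, xi, c=1.0)
        np.testing.assert_allclose(A, -0.5)
        np.testing.assert_allclose(B, lambda_xi(0.7))

    def test_one_entry_plugin(self, tiny_instance):
        Y, *_ = tiny_instance
        Y = Y.copy()
        Y.values[:] = 1
        A, B = compute_AB(Y, np.ones(Y.shape), c=1.0)
        np.testing.assert_allclose(A, 0.5)
        np.testing.assert_allclose(B, lambda_xi(1.0))
        assert B[0, 0, 0] == pytest.approx(0.11552, abs=1e-5)

    def test_B_nonnegative_any_c(self, tiny_instance, rng):
        Y, *_ = tiny_instance
        for c in (1.0, 2.0, 7.5):
            _, B = compute_AB(Y, rng.random(Y.shape) * 3, c)
            assert (B >= 0).all()

    @pytest.mark.parametrize("y,c", [(0, 1.0), (1, 1.0), (0, 3.0), (1, 3.0)])
    def test_AB_reproduce_bound_coefficients(self, y, c):
        """A z - B z^2 + const must equal the weighted local-bound expansion
        c*y*lnbound(sigma(z)) + (1-y)*lnbound(sigma(-z))."""
        xi = 1.3

        def lnbound(z_signed):
            return (
                np.log(sigmoid(xi))
                + (z_signed - xi) / 2.0
                - lambda_xi(xi) * (z_signed ** 2 - xi ** 2)
            )

        from logitcp.tensorops import AssociationTensor

        Yv = np.full((1, 1, 1), float(y))
        A, B = compute_AB(AssociationTensor(Yv), np.full((1, 1, 1), xi), c)
        w = c * y + 1 - y
        const = w * (np.log(sigmoid(xi)) - xi / 2.0 + lambda_xi(xi) * xi ** 2)
        for z in (-2.0, -0.5, 0.0, 1.0, 3.3):
            direct = c * y * lnbound(z) + (1 - y) * lnbound(-z)
            via_AB = A[0, 0, 0] * z - B[0, 0, 0] * z * z + const
            assert via_AB == pytest.approx(direct, abs=1e-12)


# ---------------------------------------------------------------------------
# expected surrogate objective restricted to single blocks (oracle functions)
# ---------------------------------------------------------------------------

def _g_row_objective(state, Y, Sm, cfg, i, g):
    """Expected surrogate objective as a function of the point value of G_i."""
    A, B = compute_AB(Y, state.xi, cfg.c)
    EH = state.H.second_moments()
    EW = state.W.second_moments()
    val = 0.0
    for j in range(Y.shape[1]):
        for k in range(Y.shape[2]):
            m1 = float(g @ (state.H.mean[j] * state.W.mean[k]))
            m2 = float(g @ (EH[j] * EW[k]) @ g)
            val += A[i, j, k] * m1 - B[i, j, k] * m2
    prior_mean = Sm.values[i] @ state.U.mean
    val -= 0.5 * state.noise.sigma_g_mean * float(((g - prior_mean) ** 2).sum())
    return val


def _w_row_objective(state, Y, cfg, k, w):
    A, B = compute_AB(Y, state.xi, cfg.c)
    EG = state.G.second_moments()
    EH = state.H.second_moments()
    val = 0.0
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            m1 = float(w @ (state.G.mean[i] * state.H.mean[j]))
            m2 = float(w @ (EG[i] * EH[j]) @ w)
            val += A[i, j, k] * m1 - B[i, j, k] * m2
    val -= 0.5 * float(w @ np.diag(state.ard.lambda_tilde) @ w)
    return val


def _u_col_objective(state, Sm, r, u):
    lam = state.ard.lambda_tilde[r]
    sg = state.noise.sigma_g_mean
    S = Sm.values
    quad = float(u @ (sg * S.T @ S + lam * np.eye(len(u))) @ u)
    lin = 2.0 * sg * float(u @ S.T @ state.G.mean[:, r])
    return -(quad - lin) / 2.0


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for a in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[a] += eps
        xm[a] -= eps
        g[a] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestGaussianUpdateStationarity:
    def test_update_G_mean_is_stationary(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=2, seed=3)
        state = randomized_state(Y, Sm, Sd, cfg)
        post = update_G(state, Y, Sm, cfg)
        for i in range(Y.shape[0]):
            grad = _num_grad(
                lambda g: _g_row_objective(state, Y, Sm, cfg, i, g), post.mean[i]
            )
            assert np.abs(grad).max() < 1e-5

    def test_update_H_mean_is_stationary(self):
        Y, Sm, Sd, cfg = make_instance(I=3, J=4, K=2, R=2, seed=4)
        state = randomized_state(Y, Sm, Sd, cfg)
        post = update_H(state, Y, Sd, cfg)
        # H plays G's role with modes permuted: reuse the G oracle on the
        # transposed problem by swapping roles explicitly
        A, B = compute_AB(Y, state.xi, cfg.c)
        EG = state.G.second_moments()
        EW = state.W.second_moments()

        def h_obj(j, h):
            val = 0.0
            for i in range(Y.shape[0]):
                for k in range(Y.shape[2]):
                    m1 = float(h @ (state.G.mean[i] * state.W.mean[k]))
                    m2 = float(h @ (EG[i] * EW[k]) @ h)
                    val += A[i, j, k] * m1 - B[i, j, k] * m2
            pm = Sd.values[j] @ state.V.mean
            val -= 0.5 * state.noise.sigma_h_mean * float(((h - pm) ** 2).sum())
            return val

        for j in range(Y.shape[1]):
            grad = _num_grad(lambda h: h_obj(j, h), post.mean[j])
            assert np.abs(grad).max() < 1e-5

    def test_update_W_mean_is_stationary(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=2, seed=5)
        state = randomized_state(Y, Sm, Sd, cfg)
        post = update_W(state, Y, cfg)
        for k in range(Y.shape[2]):
            grad = _num_grad(
                lambda w: _w_row_objective(state, Y, cfg, k, w), post.mean[k]
            )
            assert np.abs(grad).max() < 1e-5

    def test_update_U_mean_is_stationary(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=2, seed=6)
        state = randomized_state(Y, Sm, Sd, cfg)
        post = update_U(state, Sm, cfg)
        for r in range(cfg.R):
            grad = _num_grad(
                lambda u: _u_col_objective(state, Sm, r, u), post.mean[:, r]
            )
            assert np.abs(grad).max() < 1e-6

    def test_update_G_matches_numeric_maximizer(self):
        from scipy.optimize import minimize

        Y, Sm, Sd, cfg = make_instance(I=2, J=2, K=2, R=1, seed=7)
        state = randomized_state(Y, Sm, Sd, cfg)
        post = update_G(state, Y, Sm, cfg)
        for i in range(2):
            res = minimize(
                lambda g: -_g_row_objective(state, Y, Sm, cfg, i, g),
                np.zeros(1),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14},
            )
            assert abs(res.x[0] - post.mean[i, 0]) < 1e-6

    def test_covariances_symmetric_positive_definite(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=3, seed=8)
        state = randomized_state(Y, Sm, Sd, cfg)
        for post in (
            update_G(state, Y, Sm, cfg),
            update_H(state, Y, Sd, cfg),
            update_W(state, Y, cfg),
        ):
            for C in post.row_cov:
                np.testing.assert_allclose(C, C.T, atol=1e-12)
                assert np.linalg.eigvalsh(C).min() > 0


class TestClosedFormCases:
    def test_update_U_identity_similarity_closed_form(self):
        Y, Sm, Sd, cfg = make_instance(I=3, J=3, K=2, R=2, seed=9)
        from logitcp.similarity import SimilarityMatrix
        from logitcp.inference import ARDPosterior, NoisePosterior

        state = randomized_state(Y, Sm, Sd, cfg)
        state.noise = NoisePosterior(1.0, 1.0, 1.0, 1.0)  # sigma_g mean 1
        state.ard = ARDPosterior(np.ones(2), np.ones(2))  # lambda 1
        Sm_id = SimilarityMatrix(np.eye(3), Sm.entity_ids)
        post = update_U(state, Sm_id, cfg)
        np.testing.assert_allclose(post.mean, 0.5 * state.G.mean, atol=1e-12)
        for C in post.col_cov:
            np.testing.assert_allclose(C, 0.5 * np.eye(3), atol=1e-12)

    def test_update_U_zero_factor_gives_zero_mean(self):
        Y, Sm, Sd, cfg = make_instance(seed=10)
        state = randomized_state(Y, Sm, Sd, cfg)
        state.G.mean[:] = 0.0
        post = update_U(state, Sm, cfg)
        np.testing.assert_allclose(post.mean, 0.0, atol=1e-14)


class TestLambdaUpdate:
    def test_zero_moment_plugin(self):
        Y, Sm, Sd, cfg = make_instance(I=2, J=2, K=2, R=2, seed=11)
        state = randomized_state(Y, Sm, Sd, cfg)
        state.U.mean[:] = 0.0
        state.U.col_cov[:] = 0.0
        state.V.mean[:] = 0.0
        state.V.col_cov[:] = 0.0
        state.W.mean[:] = 0.0
        state.W.row_cov[:] = 0.0
        ard = update_lambda(state, cfg)
        np.testing.assert_allclose(ard.lambda_tilde, 4.0)

    def test_shape_parameter_data_independent(self):
        for seed in (1, 2):
            Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=2, seed=seed)
            state = randomized_state(Y, Sm, Sd, cfg)
            ard = update_lambda(state, cfg)
            np.testing.assert_allclose(ard.alpha_tilde, (4 + 3 + 2) / 2 + 1)

    def test_matches_independent_formula(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=2, seed=12)
        state = randomized_state(Y, Sm, Sd, cfg)
        ard = update_lambda(state, cfg)
        for r in range(cfg.R):
            uu = state.U.mean[:, r] @ state.U.mean[:, r] + np.trace(state.U.col_cov[r])
            vv = state.V.mean[:, r] @ state.V.mean[:, r] + np.trace(state.V.col_cov[r])
            ww = state.W.mean[:, r] @ state.W.mean[:, r] + sum(
                state.W.row_cov[k, r, r] for k in range(Y.shape[2])
            )
            beta = (uu + vv + ww) / 2 + cfg.beta
            assert ard.beta_tilde[r] == pytest.approx(beta, rel=1e-12)


class TestSigmaUpdate:
    def test_ratio_identity(self):
        Y, Sm, Sd, cfg = make_instance(I=3, J=3, K=2, R=2, seed=13)
        from logitcp.similarity import SimilarityMatrix
        state = randomized_state(Y, Sm, Sd, cfg)
        # engineer E||G - Sm U||^2 = I*R exactly: zero covs, unit residual
        Sm_id = SimilarityMatrix(np.eye(3), Sm.entity_ids)
        state.U.mean[:] = 0.0
        state.U.col_cov[:] = 0.0
        state.G.row_cov[:] = 0.0
        state.G.mean = np.ones((3, 2))  # ||G||^2 = 6 = I*R
        noise = update_sigma(state, Sm_id, Sd)
        assert noise.sigma_g_mean == pytest.approx(1.0)

    def test_matches_monte_carlo_expectation(self):
        Y, Sm, Sd, cfg = make_instance(I=3, J=3, K=2, R=2, seed=14)
        state = randomized_state(Y, Sm, Sd, cfg)
        from logitcp.inference import _expected_coupling_sqnorm

        analytic = _expected_coupling_sqnorm(state.G, state.U, Sm.values)
        rng = np.random.default_rng(0)
        n_draws = 100_000
        I, R = state.G.mean.shape
        total = 0.0
        G_chols = np.linalg.cholesky(state.G.row_cov)
        U_chols = np.linalg.cholesky(state.U.col_cov)
        for _ in range(200):
            m = n_draws // 200
            G = state.G.mean[None] + np.einsum(
                "iab,nib->nia", G_chols, rng.standard_normal((m, I, R))
            )
            U = state.U.mean[None] + np.einsum(
                "rab,nrb->nra", U_chols, rng.standard_normal((m, R, I))
            ).transpose(0, 2, 1)
            resid = G - np.einsum("ij,njr->nir", Sm.values, U)
            total += float((resid ** 2).sum())
        mc = total / n_draws
        assert analytic == pytest.approx(mc, rel=0.01)

    def test_monotone_in_covariance_scale(self):
        Y, Sm, Sd, cfg = make_instance(seed=15)
        state = randomized_state(Y, Sm, Sd, cfg)
        n1 = update_sigma(state, Sm, Sd)
        state.G.row_cov *= 2.0
        state.U.col_cov *= 2.0
        n2 = update_sigma(state, Sm, Sd)
        assert n2.sigma_g_mean < n1.sigma_g_mean


class TestXiUpdate:
    def test_scalar_rank1_case(self):
        Y, Sm, Sd, cfg = make_instance(I=1, J=1, K=1, R=1, seed=16)
        state = randomized_state(Y, Sm, Sd, cfg)
        state.G.mean[:] = 2.0
        state.G.row_cov[:] = 0.0
        state.H.mean[:] = 1.0
        state.H.row_cov[:] = 0.0
        state.W.mean[:] = 1.0
        state.W.row_cov[:] = 0.0
        xi = update_xi(state)
        assert xi[0, 0, 0] == pytest.approx(2.0)

    def test_zero_mean_identity_covariance_case(self):
        Y, Sm, Sd, cfg = make_instance(I=2, J=2, K=2, R=2, seed=17)
        state = randomized_state(Y, Sm, Sd, cfg)
        for f in (state.G, state.H, state.W):
            f.mean[:] = 0.0
            f.row_cov[:] = np.eye(2)
        np.testing.assert_allclose(update_xi(state), np.sqrt(2.0))

    def test_xi_squared_matches_monte_carlo_second_moment(self):
        Y, Sm, Sd, cfg = make_instance(I=2, J=2, K=2, R=2, seed=18)
        state = randomized_state(Y, Sm, Sd, cfg, scale=0.4)
        xi = update_xi(state)
        rng = np.random.default_rng(1)
        n = 600_000
        chols = {
            name: np.linalg.cholesky(f.row_cov)
            for name, f in (("G", state.G), ("H", state.H), ("W", state.W))
        }

        def draw(f, L, m):
            eps = rng.standard_normal((m, f.mean.shape[0], f.mean.shape[1]))
            return f.mean[None] + np.einsum("iab,nib->nia", L, eps)

        acc = np.zeros(Y.shape)
        chunks = 100
        for _ in range(chunks):
            m = n // chunks
            G = draw(state.G, chols["G"], m)
            H = draw(state.H, chols["H"], m)
            W = draw(state.W, chols["W"], m)
            Yt = np.einsum("nir,njr,nkr->nijk", G, H, W)
            acc += (Yt ** 2).sum(axis=0)
        mc = acc / n
        np.testing.assert_allclose(xi ** 2, mc, rtol=0.02)

    def test_equals_generalized_inner_product_of_moments(self):
        Y, Sm, Sd, cfg = make_instance(seed=19)
        state = randomized_state(Y, Sm, Sd, cfg)
        xi = update_xi(state)
        EG = state.G.second_moments()
        EH = state.H.second_moments()
        EW = state.W.second_moments()
        i, j, k = 1, 2, 1
        expected = np.sqrt(generalized_inner_product(EG[i], EH[j], EW[k]))
        assert xi[i, j, k] == pytest.approx(expected, rel=1e-12)


class TestSurrogateObjective:
    def test_column_permutation_invariance(self):
        Y, Sm, Sd, cfg = make_instance(I=4, J=3, K=2, R=3, seed=20)
        state = randomized_state(Y, Sm, Sd, cfg)
        base = surrogate_objective(state, Y, Sm, Sd, cfg)
        perm = [2, 0, 1]
        import copy

        p = copy.deepcopy(state)
        for f in (p.G, p.H, p.W):
            f.mean = f.mean[:, perm]
            f.row_cov = f.row_cov[:, perm][:, :, perm]
        for cpl in (p.U, p.V):
            cpl.mean = cpl.mean[:, perm]
            cpl.col_cov = cpl.col_cov[perm]
        p.ard.alpha_tilde = p.ard.alpha_tilde[perm]
        p.ard.beta_tilde = p.ard.beta_tilde[perm]
        assert surrogate_objective(p, Y, Sm, Sd, cfg) == pytest.approx(
            base, rel=1e-12
        )

    def test_matches_independent_reimplementation(self):
        from elbo_oracle import elbo_by_loops

        Y, Sm, Sd, cfg = make_instance(I=3, J=3, K=2, R=2, seed=21)
        state = randomized_state(Y, Sm, Sd, cfg)
        fast = surrogate_objective(state, Y, Sm, Sd, cfg)
        slow = elbo_by_loops(state, Y, Sm, Sd, cfg)
        assert fast == pytest.approx(slow, abs=1e-8)


class TestPredict:
    def test_zero_means_give_half(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        state = initialize_state(Y, Sm, Sd, cfg)
        state.G.mean[:] = 0.0
        np.testing.assert_allclose(predict(state), 0.5)

    def test_composition_of_sigmoid_and_cp(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        state = randomized_state(Y, Sm, Sd, cfg)
        expected = sigmoid(
            cp_reconstruct(state.G.mean, state.H.mean, state.W.mean)
        )
        np.testing.assert_allclose(predict(state), expected)

    def test_monotone_in_single_mean_entry(self, tiny_instance):
        Y, Sm, Sd, cfg = tiny_instance
        state = randomized_state(Y, Sm, Sd, cfg)
        state.H.mean[0, 0] = 1.0
        state.W.mean[0, 0] = 1.0
        p0 = predict(state)[0, 0, 0]
        state.G.mean[0, 0] += 0.5
        assert predict(state)[0, 0, 0] > p0
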