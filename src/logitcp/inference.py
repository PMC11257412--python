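"""Mean-field variational inference for Bayesian logistic CP decomposition.

Model
-----
A binary tensor ``Y`` (I miRNAs × J diseases × K types) is modelled through a
CP reconstruction ``Ytilde[i,j,k] = sum_r G[i,r] H[j,r] W[k,r]`` and a
weighted Bernoulli-logistic likelihood::

    P(Y | G, H, W) = prod_ijk sigma(Ytilde)^(c·Y) (1 - sigma(Ytilde))^(1 - Y)

with importance weight ``c >= 1`` on known positives.  Kernel coupling priors
tie the miRNA/disease factors to similarity matrices,
``G[i,r] ~ N(S^m[i,:] U[:,r], 1/sigma_g)`` (and H to S^d via V), with Jeffreys
priors on the precisions.  Columns of U, V and W share per-component Gamma
precisions ``lambda_r`` (automatic rank determination): components the data do
not support get large posterior precision and shrink to zero.

Inference replaces each log-sigmoid with its local quadratic lower bound
(parameter ``xi``), making every conditional conjugate; coordinate ascent on
the resulting surrogate evidence lower bound updates, in order, the noise
precisions, the factor rows, the coupling columns, the ARD precisions and the
local bound parameters.  The surrogate objective is monotone non-decreasing
over sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma, gammaln

from .similarity import SimilarityMatrix
from .tensorops import (
    AssociationTensor,
    cp_reconstruct,
    khatri_rao,
    lambda_xi,
    sigmoid,
    unfold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FactorPosterior",
    "CouplingPosterior",
    "ARDPosterior",
    "NoisePosterior",
    "VariationalState",
    "initialize_state",
    "compute_AB",
    "update_G",
    "update_H",
    "update_W",
    "update_U",
    "update_V",
    "update_lambda",
    "update_sigma",
    "update_xi",
    "surrogate_objective",
    "fit",
    "effective_rank",
    "predict",
]


# ---------------------------------------------------------------------------
# configuration and posterior containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and run controls for the variational fit.

    Parameters
    ----------
    R : initial number of CP components; ARD shrinks the surplus.
    c : importance weight (>= 1) on known positive triples.
    alpha, beta : Gamma hyperparameters of the ARD precisions (1, 1 is the
        uninformative default).
    max_iter, tol : stop after ``max_iter`` sweeps or when the relative change
        of the surrogate objective drops below ``tol``.
    seed : seed for the random initialization.
    jitter : initial diagonal jitter for precision inversions.
    """

    R: int = 20
    c: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    jitter: float = 1e-10

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.c < 1:
            raise ValueError("importance weight c must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Gamma hyperparameters must be positive")


@dataclass
class FactorPosterior:
    """Row-wise Gaussian posterior of a factor matrix (mean n×R, n R×R covs)."""

    mean: np.ndarray
    row_cov: np.ndarray  # (n, R, R)

    def second_moments(self) -> np.ndarray:
        """Stack of E[row^T row] = mean_i^T mean_i + cov_i, shape (n, R, R)."""
        m = self.mean
        return m[:, :, None] * m[:, None, :] + self.row_cov


@dataclass
class CouplingPosterior:
    """Column-wise Gaussian posterior of a coupling matrix (R n×n covs)."""

    mean: np.ndarray
    col_cov: np.ndarray  # (R, n, n)

    def col_sqnorms(self) -> np.ndarray:
        """E[||col_r||^2] = ||mean_r||^2 + tr cov_r, shape (R,)."""
        return (self.mean ** 2).sum(axis=0) + np.trace(
            self.col_cov, axis1=1, axis2=2
        )

    def row_second_moments(self) -> np.ndarray:
        """Diagonal-approximation row moments E[row^T row], shape (n, R, R).

        Columns are independent under the posterior, so the cross terms are
        exact products of means and the diagonal collects the variances.
        """
        m = self.mean
        out = m[:, :, None] * m[:, None, :]
        var = np.stack([np.diag(C) for C in self.col_cov], axis=1)  # (n, R)
        idx = np.arange(m.shape[1])
        out[:, idx, idx] += var
        return out


@dataclass
class ARDPosterior:
    """Gamma posteriors of the per-component precisions lambda_r."""

    alpha_tilde: np.ndarray
    beta_tilde: np.ndarray

    @property
    def lambda_tilde(self) -> np.ndarray:
        return self.alpha_tilde / self.beta_tilde

    @property
    def ln_lambda_tilde(self) -> np.ndarray:
        return digamma(self.alpha_tilde) - np.log(self.beta_tilde)


@dataclass
class NoisePosterior:
    """Gamma posteriors of the coupling precisions sigma_g, sigma_h."""

    a_g: float
    b_g: float
    a_h: float
    b_h: float

    @property
    def sigma_g_mean(self) -> float:
        return self.a_g / self.b_g

    @property
    def sigma_h_mean(self) -> float:
        return self.a_h / self.b_h

    @property
    def ln_sigma_g(self) -> float:
        return float(digamma(self.a_g) - np.log(self.b_g))

    @property
    def ln_sigma_h(self) -> float:
        return float(digamma(self.a_h) - np.log(self.b_h))


@dataclass
class VariationalState:
    """All posterior summaries plus the surrogate-objective trace."""

    G: FactorPosterior
    H: FactorPosterior
    W: FactorPosterior
    U: CouplingPosterior
    V: CouplingPosterior
    ard: ARDPosterior
    noise: NoisePosterior
    xi: np.ndarray
    objective_trace: list = field(default_factory=list)
    iteration: int = 0

    @property
    def shape(self):
        I = self.G.mean.shape[0]
        J = self.H.mean.shape[0]
        K = self.W.mean.shape[0]
        return I, J, K

    @property
    def rank(self) -> int:
        return self.G.mean.shape[1]


# ---------------------------------------------------------------------------
# numerics helpers
# ---------------------------------------------------------------------------

def _invert_spd_stack(P: np.ndarray, jitter: float) -> np.ndarray:
    """Invert a stack of symmetric positive-definite matrices.

    On Cholesky failure the diagonal jitter escalates tenfold up to 1e-6
    before giving up.
    """
    P = 0.5 * (P + np.swapaxes(P, -1, -2))
    eye = np.eye(P.shape[-1])
    j = 0.0
    while True:
        try:
            L = np.linalg.cholesky(P + j * eye)
            inv = np.linalg.inv(P + j * eye)
            del L
            break
        except np.linalg.LinAlgError:
            j = jitter if j == 0.0 else j * 10.0
            if j > 1e-6:
                raise np.linalg.LinAlgError(
                    "precision matrix not positive definite even with jitter 1e-6"
                )
            logger.warning("singular precision: adding diagonal jitter %g", j)
    return 0.5 * (inv + np.swapaxes(inv, -1, -2))


def _logdet_spd(C: np.ndarray) -> np.ndarray:
    """log-determinants of a stack of SPD matrices."""
    sign, logdet = np.linalg.slogdet(C)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("covariance with non-positive determinant")
    return logdet


def _check_alignment(Y: AssociationTensor, Sm: SimilarityMatrix, Sd: SimilarityMatrix):
    if Sm.entity_ids != Y.mirna_ids:
        bad = [a for a, b in zip(Sm.entity_ids, Y.mirna_ids) if a != b]
        raise ValueError(
            f"miRNA similarity registry misaligned with tensor (first offenders: {bad[:5]})"
        )
    if Sd.entity_ids != Y.disease_ids:
        bad = [a for a, b in zip(Sd.entity_ids, Y.disease_ids) if a != b]
        raise ValueError(
            f"disease similarity registry misaligned with tensor (first offenders: {bad[:5]})"
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_state(
    Y: AssociationTensor,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    cfg: ModelConfig,
) -> VariationalState:
    """Random standard-normal means, identity covariances, xi = 1 everywhere."""
    _check_alignment(Y, Sm, Sd)
    I, J, K = Y.shape
    R = cfg.R
    rng = np.random.default_rng(cfg.seed)
    eyeR = np.eye(R)

    def factor(n):
        return FactorPosterior(
            rng.standard_normal((n, R)), np.tile(eyeR, (n, 1, 1))
        )

    def coupling(n):
        return CouplingPosterior(
            rng.standard_normal((n, R)), np.tile(np.eye(n), (R, 1, 1))
        )

    return VariationalState(
        G=factor(I),
        H=factor(J),
        W=factor(K),
        U=coupling(I),
        V=coupling(J),
        ard=ARDPosterior(np.ones(R), np.ones(R)),
        noise=NoisePosterior(1.0, 1.0, 1.0, 1.0),
        xi=np.ones((I, J, K)),
    )


# ---------------------------------------------------------------------------
# update equations
# ---------------------------------------------------------------------------

def compute_AB(Y: AssociationTensor, xi: np.ndarray, c: float):
    """Auxiliary tensors of the bounded likelihood.

    ``A = ((c+1)Y - 1) / 2`` collects the linear coefficients and
    ``B = (1 + (c-1)Y) * lambda(xi)`` the (nonnegative) quadratic ones.
    """
    Yv = Y.values if isinstance(Y, AssociationTensor) else np.asarray(Y)
    if Yv.shape != np.shape(xi):
        raise ValueError(f"shape mismatch: Y {Yv.shape} vs xi {np.shape(xi)}")
    A = ((c + 1.0) * Yv - 1.0) / 2.0
    B = (1.0 + (c - 1.0) * Yv) * lambda_xi(np.asarray(xi))
    return A, B


def update_G(
    state: VariationalState,
    Y: AssociationTensor,
    Sm: SimilarityMatrix,
    cfg: ModelConfig,
) -> FactorPosterior:
    """Row-wise Gaussian update of the miRNA factor G."""
    A, B = compute_AB(Y, state.xi, cfg.c)
    EH = state.H.second_moments()
    EW = state.W.second_moments()
    sg = state.noise.sigma_g_mean
    R = state.rank
    prec = 2.0 * np.einsum("ijk,jab,kab->iab", B, EH, EW)
    prec += sg * np.eye(R)
    cov = _invert_spd_stack(prec, cfg.jitter)
    rhs = unfold(A, 1) @ khatri_rao(state.W.mean, state.H.mean)
    rhs += sg * (Sm.values @ state.U.mean)
    mean = np.einsum("iab,ib->ia", cov, rhs)
    return FactorPosterior(mean, cov)


def update_H(
    state: VariationalState,
    Y: AssociationTensor,
    Sd: SimilarityMatrix,
    cfg: ModelConfig,
) -> FactorPosterior:
    """Row-wise Gaussian update of the disease factor H."""
    A, B = compute_AB(Y, state.xi, cfg.c)
    EG = state.G.second_moments()
    EW = state.W.second_moments()
    sh = state.noise.sigma_h_mean
    R = state.rank
    prec = 2.0 * np.einsum("ijk,kab,iab->jab", B, EW, EG)
    prec += sh * np.eye(R)
    cov = _invert_spd_stack(prec, cfg.jitter)
    rhs = unfold(A, 2) @ khatri_rao(state.W.mean, state.G.mean)
    rhs += sh * (Sd.values @ state.V.mean)
    mean = np.einsum("jab,jb->ja", cov, rhs)
    return FactorPosterior(mean, cov)


def update_W(
    state: VariationalState,
    Y: AssociationTensor,
    cfg: ModelConfig,
) -> FactorPosterior:
    """Row-wise Gaussian update of the type factor W (ARD prior diag(lambda))."""
    A, B = compute_AB(Y, state.xi, cfg.c)
    EG = state.G.second_moments()
    EH = state.H.second_moments()
    prec = 2.0 * np.einsum("ijk,iab,jab->kab", B, EG, EH)
    prec += np.diag(state.ard.lambda_tilde)
    cov = _invert_spd_stack(prec, cfg.jitter)
    rhs = unfold(A, 3) @ khatri_rao(state.H.mean, state.G.mean)
    mean = np.einsum("kab,kb->ka", cov, rhs)
    return FactorPosterior(mean, cov)


def _coupling_update(S, factor_mean, sigma_mean, lam, jitter, eig=None):
    n, R = factor_mean.shape
    M = S.T @ S
    if eig is None:
        d, Q = np.linalg.eigh(0.5 * (M + M.T))
        d = np.maximum(d, 0.0)
    else:
        d, Q = eig
    T = Q.T @ (S.T @ factor_mean)  # (n, R)
    denom = sigma_mean * d[:, None] + lam[None, :]  # (n, R)
    mean = sigma_mean * (Q @ (T / denom))
    cov = np.einsum("ia,ar,ja->rij", Q, 1.0 / denom, Q)
    return CouplingPosterior(mean, cov)


def update_U(
    state: VariationalState,
    Sm: SimilarityMatrix,
    cfg: ModelConfig,
    eig=None,
) -> CouplingPosterior:
    """Column-wise Gaussian update of the miRNA coupling matrix U.

    ``eig`` may carry a precomputed eigendecomposition of S^m.T S^m; the fit
    loop reuses it across sweeps since the similarity matrix is fixed.
    """
    return _coupling_update(
        Sm.values, state.G.mean, state.noise.sigma_g_mean,
        state.ard.lambda_tilde, cfg.jitter, eig,
    )


def update_V(
    state: VariationalState,
    Sd: SimilarityMatrix,
    cfg: ModelConfig,
    eig=None,
) -> CouplingPosterior:
    """Column-wise Gaussian update of the disease coupling matrix V."""
    return _coupling_update(
        Sd.values, state.H.mean, state.noise.sigma_h_mean,
        state.ard.lambda_tilde, cfg.jitter, eig,
    )


def update_lambda(state: VariationalState, cfg: ModelConfig) -> ARDPosterior:
    """Gamma update of the ARD precisions shared by U, V and W columns."""
    I, J, K = state.shape
    R = state.rank
    alpha_tilde = np.full(R, (I + J + K) / 2.0 + cfg.alpha)
    ww = (state.W.mean ** 2).sum(axis=0) + np.einsum("krr->r", state.W.row_cov)
    beta_tilde = (
        state.U.col_sqnorms() + state.V.col_sqnorms() + ww
    ) / 2.0 + cfg.beta
    return ARDPosterior(alpha_tilde, beta_tilde)


def _expected_coupling_sqnorm(
    F: FactorPosterior, C: CouplingPosterior, S: np.ndarray
) -> float:
    """E||F - S C||_F^2 under the factorized posterior."""
    resid = F.mean - S @ C.mean
    val = float((resid ** 2).sum())
    val += float(np.einsum("irr->", F.row_cov))
    # tr(S (sum_r cov_r) S^T)
    val += float(np.einsum("ij,rjk,ik->", S, C.col_cov, S))
    return val


def update_sigma(
    state: VariationalState,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
) -> NoisePosterior:
    """Gamma updates of the coupling precisions (Jeffreys priors).

    Posterior mean is IR / E||G - S^m U||^2 (and JR / ... for sigma_h); the
    expected squared norm is floored at 1e-12 against degenerate exact fits.
    """
    I, J, K = state.shape
    R = state.rank
    Eg = _expected_coupling_sqnorm(state.G, state.U, Sm.values)
    Eh = _expected_coupling_sqnorm(state.H, state.V, Sd.values)
    floor = 1e-12
    if Eg < floor or Eh < floor:
        logger.warning("expected coupling residual clamped at %g (exact fit)", floor)
    return NoisePosterior(
        a_g=I * R / 2.0, b_g=max(Eg, floor) / 2.0,
        a_h=J * R / 2.0, b_h=max(Eh, floor) / 2.0,
    )


def _second_moment_tensor(state: VariationalState) -> np.ndarray:
    """E[Ytilde^2] elementwise, via the generalized inner product of the
    per-row second moments of G, H and W."""
    EG = state.G.second_moments()
    EH = state.H.second_moments()
    EW = state.W.second_moments()
    return np.einsum("iab,jab,kab->ijk", EG, EH, EW)


def update_xi(state: VariationalState) -> np.ndarray:
    """Optimal local bound parameters: xi = sqrt(E[Ytilde^2]) (nonneg root)."""
    return np.sqrt(np.maximum(_second_moment_tensor(state), 0.0))


# ---------------------------------------------------------------------------
# surrogate objective (bounded ELBO)
# ---------------------------------------------------------------------------

def surrogate_objective(
    state: VariationalState,
    Y: AssociationTensor,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    cfg: ModelConfig,
) -> float:
    """Evidence lower bound with the local sigmoid bound substituted.

    Used for convergence monitoring and monotonicity testing only; additive
    constants that depend on fixed dimensions are included so independent
    re-implementations can match term by term.
    """
    I, J, K = state.shape
    R = state.rank
    Yv = Y.values
    c = cfg.c
    xi = state.xi
    w = 1.0 + (c - 1.0) * Yv
    A, B = compute_AB(Y, xi, c)

    M1 = cp_reconstruct(state.G.mean, state.H.mean, state.W.mean)
    M2 = _second_moment_tensor(state)
    # expected bounded log-likelihood
    log_sig_xi = np.log(sigmoid(xi))
    ll = float(
        np.sum(A * M1 - B * M2 + w * (log_sig_xi - xi / 2.0) + B * xi ** 2)
    )

    ln2pi = np.log(2.0 * np.pi)
    noise = state.noise
    ard = state.ard
    lam = ard.lambda_tilde
    ln_lam = ard.ln_lambda_tilde

    # coupling priors on G, H
    Eg = _expected_coupling_sqnorm(state.G, state.U, Sm.values)
    Eh = _expected_coupling_sqnorm(state.H, state.V, Sd.values)
    prior_G = 0.5 * I * R * (noise.ln_sigma_g - ln2pi) - 0.5 * noise.sigma_g_mean * Eg
    prior_H = 0.5 * J * R * (noise.ln_sigma_h - ln2pi) - 0.5 * noise.sigma_h_mean * Eh

    # ARD priors on U, V, W columns
    uu = state.U.col_sqnorms()
    vv = state.V.col_sqnorms()
    ww = (state.W.mean ** 2).sum(axis=0) + np.einsum("krr->r", state.W.row_cov)
    prior_U = float(np.sum(0.5 * I * (ln_lam - ln2pi) - 0.5 * lam * uu))
    prior_V = float(np.sum(0.5 * J * (ln_lam - ln2pi) - 0.5 * lam * vv))
    prior_W = float(np.sum(0.5 * K * (ln_lam - ln2pi) - 0.5 * lam * ww))

    # Gamma prior on lambda; Jeffreys priors on sigma_g, sigma_h
    prior_lam = float(
        np.sum(
            cfg.alpha * np.log(cfg.beta)
            - gammaln(cfg.alpha)
            + (cfg.alpha - 1.0) * ln_lam
            - cfg.beta * lam
        )
    )
    prior_sigma = -noise.ln_sigma_g - noise.ln_sigma_h

    # entropies
    ent_G = 0.5 * float(np.sum(_logdet_spd(state.G.row_cov))) + 0.5 * I * R * (1 + ln2pi)
    ent_H = 0.5 * float(np.sum(_logdet_spd(state.H.row_cov))) + 0.5 * J * R * (1 + ln2pi)
    ent_W = 0.5 * float(np.sum(_logdet_spd(state.W.row_cov))) + 0.5 * K * R * (1 + ln2pi)
    ent_U = 0.5 * float(np.sum(_logdet_spd(state.U.col_cov))) + 0.5 * I * R * (1 + ln2pi)
    ent_V = 0.5 * float(np.sum(_logdet_spd(state.V.col_cov))) + 0.5 * J * R * (1 + ln2pi)

    def gamma_entropy(a, b):
        return a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)

    ent_lam = float(np.sum(gamma_entropy(ard.alpha_tilde, ard.beta_tilde)))
    ent_sig = float(
        gamma_entropy(noise.a_g, noise.b_g) + gamma_entropy(noise.a_h, noise.b_h)
    )

    return (
        ll
        + prior_G + prior_H + prior_U + prior_V + prior_W
        + prior_lam + prior_sigma
        + ent_G + ent_H + ent_W + ent_U + ent_V + ent_lam + ent_sig
    )


# ---------------------------------------------------------------------------
# main loop, rank report, prediction
# ---------------------------------------------------------------------------

def fit(
    Y: AssociationTensor,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    cfg: ModelConfig,
    callback=None,
) -> VariationalState:
    """Run the coordinate-ascent sweep until convergence.

    Sweep order: noise precisions, then G, H, W, then U, V, then the ARD
    precisions per component, then the local bound parameters xi.  Stops when
    the relative objective change drops below ``cfg.tol`` or after
    ``cfg.max_iter`` sweeps.  Deterministic given ``cfg.seed``.
    """
    _check_alignment(Y, Sm, Sd)
    state = initialize_state(Y, Sm, Sd, cfg)
    Mm = Sm.values.T @ Sm.values
    dm, Qm = np.linalg.eigh(0.5 * (Mm + Mm.T))
    eig_m = (np.maximum(dm, 0.0), Qm)
    Md = Sd.values.T @ Sd.values
    dd, Qd = np.linalg.eigh(0.5 * (Md + Md.T))
    eig_d = (np.maximum(dd, 0.0), Qd)

    prev = None
    for it in range(1, cfg.max_iter + 1):
        for name, step in (
            ("sigma", lambda: replace_field(state, "noise", update_sigma(state, Sm, Sd))),
            ("G", lambda: replace_field(state, "G", update_G(state, Y, Sm, cfg))),
            ("H", lambda: replace_field(state, "H", update_H(state, Y, Sd, cfg))),
            ("W", lambda: replace_field(state, "W", update_W(state, Y, cfg))),
            ("U", lambda: replace_field(state, "U", update_U(state, Sm, cfg, eig_m))),
            ("V", lambda: replace_field(state, "V", update_V(state, Sd, cfg, eig_d))),
            ("lambda", lambda: replace_field(state, "ard", update_lambda(state, cfg))),
            ("xi", lambda: replace_field(state, "xi", update_xi(state))),
        ):
            state = step()
            if not _state_finite(state):
                raise FloatingPointError(
                    f"non-finite values after the '{name}' update at sweep {it}"
                )
        obj = surrogate_objective(state, Y, Sm, Sd, cfg)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite surrogate objective at sweep {it}"
            )
        state.objective_trace.append(obj)
        state.iteration = it
        if callback is not None:
            callback(state)
        logger.debug(
            "sweep %d: objective=%.6f lambda=%s", it, obj,
            np.array2string(state.ard.lambda_tilde, precision=2),
        )
        if prev is not None and abs(obj - prev) <= cfg.tol * abs(prev):
            break
        prev = obj
    return state


def replace_field(state: VariationalState, name: str, value) -> VariationalState:
    """Functional single-field replacement preserving trace and counters."""
    return replace(state, **{name: value})


def _state_finite(state: VariationalState) -> bool:
    arrays = (
        state.G.mean, state.H.mean, state.W.mean,
        state.U.mean, state.V.mean,
        state.ard.alpha_tilde, state.ard.beta_tilde, state.xi,
    )
    return all(np.isfinite(a).all() for a in arrays) and np.isfinite(
        [state.noise.b_g, state.noise.b_h]
    ).all()


def effective_rank(state: VariationalState, threshold_ratio: float = 100.0):
    """ARD-based effective rank: retained components and their count.

    A component is shrunk when its ARD precision grows and the posterior
    means of the corresponding U, V and W columns collapse to zero; the
    mean-mass spectrum ``m_r = E||U_r||^2 + E||V_r||^2 + E||W_r||^2`` (means
    only) separates live from dead components by hundreds of orders of
    magnitude, whereas the precision means themselves saturate at a
    covariance-floor plateau.  Component ``r`` is therefore retained iff
    ``m_r >= max(m) / threshold_ratio``.  Purely diagnostic; no column is
    ever removed during inference.

    Returns ``(count, retained_indices)``.
    """
    mass = (
        (state.U.mean ** 2).sum(axis=0)
        + (state.V.mean ** 2).sum(axis=0)
        + (state.W.mean ** 2).sum(axis=0)
    )
    ref = float(np.max(mass))
    if ref == 0.0 or not np.isfinite(threshold_ratio):
        retained = list(range(len(mass)))
    else:
        retained = [int(r) for r in np.flatnonzero(mass >= ref / threshold_ratio)]
    return len(retained), retained


def predict(state: VariationalState) -> np.ndarray:
    """Posterior-mean association probabilities sigma(<G~, H~, W~>)."""
    return sigmoid(cp_reconstruct(state.G.mean, state.H.mean, state.W.mean))
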