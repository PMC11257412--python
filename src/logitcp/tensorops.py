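"""Tensor algebra primitives shared by all pipeline stages.

Conventions
-----------
A third-order tensor ``T`` of shape ``(I, J, K)`` indexes (miRNA i, disease j,
association-type k).  Mode-n unfolding uses the ordering under which, for a CP
model with factors ``G (I×R)``, ``H (J×R)``, ``W (K×R)``::

    unfold(T, 1) = G @ khatri_rao(W, H).T      # I  × JK, column j + k*J
    unfold(T, 2) = H @ khatri_rao(W, G).T      # J  × IK, column i + k*I
    unfold(T, 3) = W @ khatri_rao(H, G).T      # K  × IJ, column i + j*I

i.e. the lower-numbered remaining mode varies fastest along columns, and
``khatri_rao(A, B)`` stacks B's index fastest along rows.  All indexing is
0-based internally; axis labels are carried by :class:`AssociationTensor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import khatri_rao as _scipy_khatri_rao

__all__ = [
    "AssociationTensor",
    "unfold",
    "khatri_rao",
    "cp_reconstruct",
    "generalized_inner_product",
    "sigmoid",
    "lambda_xi",
]


def _check_unique(labels, axis_name):
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {axis_name} labels: {dupes[:5]}")
    return labels


@dataclass
class AssociationTensor:
    """Binary I×J×K association tensor Y with axis label registries.

    ``values[i, j, k] == 1`` iff miRNA *i* is associated with disease *j*
    under association type *k*.
    """

    values: np.ndarray
    mirna_ids: list = field(default_factory=list)
    disease_ids: list = field(default_factory=list)
    type_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-way tensor, got ndim={self.values.ndim}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association tensor entries must be 0 or 1")
        self.values = self.values.astype(np.float64)
        I, J, K = self.values.shape
        if min(I, J, K) < 1:
            raise ValueError("all tensor dimensions must be >= 1")
        if not self.mirna_ids:
            self.mirna_ids = [f"mirna-{i}" for i in range(I)]
        if not self.disease_ids:
            self.disease_ids = [f"disease-{j}" for j in range(J)]
        if not self.type_names:
            self.type_names = [f"type-{k}" for k in range(K)]
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.type_names = _check_unique(self.type_names, "type")
        for labels, n, name in (
            (self.mirna_ids, I, "miRNA"),
            (self.disease_ids, J, "disease"),
            (self.type_names, K, "type"),
        ):
            if len(labels) != n:
                raise ValueError(
                    f"{name} registry length {len(labels)} != axis length {n}"
                )

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_known(self) -> int:
        """Number of known (positive) triples."""
        return int(self.values.sum())

    @property
    def density(self) -> float:
        """Fraction of entries that are known positives."""
        return self.n_known / self.values.size

    def copy(self) -> "AssociationTensor":
        return AssociationTensor(
            self.values.copy(),
            list(self.mirna_ids),
            list(self.disease_ids),
            list(self.type_names),
        )


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization of a 3-way tensor.

    Parameters
    ----------
    t : ndarray of shape (I, J, K)
    mode : {1, 2, 3}
        Mode whose fibers become rows.

    Returns
    -------
    ndarray
        ``I×JK`` (mode 1), ``J×IK`` (mode 2) or ``K×IJ`` (mode 3); see the
        module docstring for the column ordering.
    """
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={t.ndim}")
    I, J, K = t.shape
    if mode == 1:
        return t.transpose(0, 2, 1).reshape(I, K * J)
    if mode == 2:
        return t.transpose(1, 2, 0).reshape(J, K * I)
    if mode == 3:
        return t.transpose(2, 1, 0).reshape(K, J * I)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker (Khatri-Rao) product, ``PQ×R`` from ``P×R, Q×R``.

    Row ``i*Q + q`` holds ``A[i, :] * B[q, :]`` (B's index fastest), matching
    the unfolding convention above.
    """
    A = np.asarray(A)
    B = np.asarray(B)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("khatri_rao expects two matrices")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column-count mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    return _scipy_khatri_rao(A, B)


def cp_reconstruct(G: np.ndarray, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Reconstruct the I×J×K tensor with entries sum_r G[i,r] H[j,r] W[k,r]."""
    G, H, W = (np.asarray(M) for M in (G, H, W))
    if not (G.ndim == H.ndim == W.ndim == 2):
        raise ValueError("factors must be matrices")
    if not (G.shape[1] == H.shape[1] == W.shape[1]):
        raise ValueError(
            "factor rank mismatch: "
            f"{G.shape[1]}, {H.shape[1]}, {W.shape[1]}"
        )
    return np.einsum("ir,jr,kr->ijk", G, H, W)


def generalized_inner_product(M1: np.ndarray, M2: np.ndarray, M3: np.ndarray) -> float:
    """Sum over all entries of the elementwise (Hadamard) triple product."""
    M1, M2, M3 = (np.asarray(M) for M in (M1, M2, M3))
    if not (M1.shape == M2.shape == M3.shape):
        raise ValueError(
            f"shape mismatch: {M1.shape}, {M2.shape}, {M3.shape}"
        )
    return float(np.sum(M1 * M2 * M3))


def sigmoid(x):
    """Numerically stable logistic function sigma(x) = 1/(1+exp(-x))."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def lambda_xi(xi):
    """Curvature lambda(xi) = (sigma(xi) - 1/2) / (2 xi) of the logistic bound.

    Even and strictly positive; the removable singularity at 0 is filled with
    the series limit 1/8.
    """
    xi = np.asarray(xi, dtype=np.float64)
    scalar = xi.ndim == 0
    xi = np.atleast_1d(np.abs(xi))
    out = np.full_like(xi, 0.125)
    nz = xi > 1e-6
    out[nz] = (sigmoid(xi[nz]) - 0.5) / (2.0 * xi[nz])
    if scalar:
        return float(out[0])
    return out.reshape(np.shape(xi))
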