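"""Similarity-network construction and fusion.

Three sources of pairwise similarity feed the decomposition model:

* miRNA *functional* similarity, computed from miRNA–gene associations plus a
  gene functional network scored with log-likelihood scores (LLS): gene-gene
  similarity is the min–max scaled LLS, and miRNA-level similarity averages
  best-match gene similarities across both gene sets.
* *interaction-profile* similarity for miRNAs and diseases, obtained by
  reducing the mode-1 / mode-2 unfoldings of the association tensor to
  nonnegative low-dimensional features (NNDSVD) and applying a kernel
  neighborhood similarity to the feature rows.
* disease *semantic* similarity, consumed as a precomputed input file.

Per-entity sources are then fused into the final S^m and S^d matrices.  The
kernel-neighborhood and fusion steps are pluggable; the defaults documented
here (Gaussian kernel restricted to nearest neighbors; convex combination)
preserve the contracts every downstream stage relies on: symmetry, entries in
[0, 1] and a unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tensorops import AssociationTensor, unfold

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "MiRNAGeneMap",
    "SimilarityMatrix",
    "FeatureMatrix",
    "gene_similarity",
    "mirna_functional_similarity",
    "nndsvd",
    "profile_features",
    "interaction_profile_similarity",
    "fuse_similarities",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Gene functional network with log-likelihood-score (LLS) edge weights."""

    gene_ids: list
    edges: list  # (gene_a, gene_b, lls)

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        self._lls = {}
        scores = []
        for a, b, s in self.edges:
            s = float(s)
            self._lls[(a, b)] = s
            self._lls[(b, a)] = s
            scores.append(s)
        self.lls_min = min(scores) if scores else 0.0
        self.lls_max = max(scores) if scores else 0.0

    def has_gene(self, g) -> bool:
        return g in self._index

    def lls(self, g1, g2):
        """Edge score between two genes, or None when no edge exists."""
        return self._lls.get((g1, g2))


@dataclass
class MiRNAGeneMap:
    """Mapping from each miRNA id to its associated gene set."""

    mapping: dict  # mirna id -> set of gene ids

    def __post_init__(self):
        self.mapping = {m: set(gs) for m, gs in self.mapping.items()}

    @property
    def mirna_ids(self):
        return list(self.mapping)

    def genes(self, mirna) -> set:
        return self.mapping[mirna]


@dataclass
class SimilarityMatrix:
    """Labeled square similarity matrix: symmetric, unit diagonal, in [0, 1]."""

    values: np.ndarray
    entity_ids: list = field(default_factory=list)

    _SYM_TOL = 1e-10

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {self.values.shape}")
        n = self.values.shape[0]
        if not self.entity_ids:
            self.entity_ids = [f"entity-{i}" for i in range(n)]
        self.entity_ids = list(self.entity_ids)
        if len(self.entity_ids) != n:
            raise ValueError(
                f"registry length {len(self.entity_ids)} != matrix size {n}"
            )
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids in similarity registry")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > self._SYM_TOL:
            raise ValueError("similarity matrix is not symmetric within 1e-10")
        if self.values.min(initial=0.0) < -1e-12 or self.values.max(initial=1.0) > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reindexed(self, ids) -> "SimilarityMatrix":
        """Return a copy reindexed to the given id order (must be a permutation)."""
        ids = list(ids)
        missing = [g for g in ids if g not in set(self.entity_ids)]
        if missing:
            raise ValueError(f"ids absent from similarity registry: {missing[:5]}")
        pos = {g: i for i, g in enumerate(self.entity_ids)}
        idx = np.array([pos[g] for g in ids])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], ids)


@dataclass
class FeatureMatrix:
    """Nonnegative n×d feature matrix with an entity registry."""

    values: np.ndarray
    entity_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.min(initial=0.0) < -1e-12:
            raise ValueError("feature matrix must be nonnegative")
        self.values = np.maximum(self.values, 0.0)
        n = self.values.shape[0]
        if not self.entity_ids:
            self.entity_ids = [f"entity-{i}" for i in range(n)]
        self.entity_ids = list(self.entity_ids)
        if len(self.entity_ids) != n:
            raise ValueError("registry length mismatch")


# ---------------------------------------------------------------------------
# miRNA functional similarity from a gene network
# ---------------------------------------------------------------------------

def gene_similarity(net: GeneNetwork, g1, g2) -> float:
    """Min–max scaled LLS similarity between two genes.

    1 for identical genes, 0 when no edge connects them, otherwise
    ``(LLS - LLS_min) / (LLS_max - LLS_min)``.  Genes absent from the network
    have no edges, hence similarity 0 to everything else.
    """
    if g1 == g2:
        return 1.0
    s = net.lls(g1, g2)
    if s is None:
        return 0.0
    span = net.lls_max - net.lls_min
    if span <= 0:
        # all edges share one score: degenerate scaling, treat as full support
        logger.warning("degenerate LLS scaling (min == max); edge similarity set to 1")
        return 1.0
    return (s - net.lls_min) / span


def _best_match(net: GeneNetwork, g, gene_set) -> float:
    return max(gene_similarity(net, g, g2) for g2 in gene_set)


def mirna_functional_similarity(gmap: MiRNAGeneMap, net: GeneNetwork) -> SimilarityMatrix:
    """Functional similarity between miRNAs via best-match gene similarity.

    For gene sets G_i, G_j the similarity is::

        [ sum_{g in G_i} S(g, G_j) + sum_{g in G_j} S(g, G_i) ] / (|G_i| + |G_j|)

    with ``S(g, G) = max_{g' in G} S(g, g')``.  miRNAs with empty gene sets get
    zero off-diagonal similarity; the diagonal is 1 by definition.
    """
    mirnas = gmap.mirna_ids
    if not any(gmap.genes(m) for m in mirnas):
        raise ValueError("at least one miRNA must have a nonempty gene set")
    unmatched = sorted(
        {g for m in mirnas for g in gmap.genes(m) if not net.has_gene(g)}
    )
    if unmatched:
        logger.warning(
            "%d mapped genes absent from the gene network (zero similarity): %s",
            len(unmatched), unmatched[:5],
        )
    empty = [m for m in mirnas if not gmap.genes(m)]
    if empty:
        logger.warning("miRNAs with empty gene sets get zero similarity: %s", empty[:5])
    n = len(mirnas)
    S = np.eye(n)
    for i in range(n):
        Gi = gmap.genes(mirnas[i])
        for j in range(i + 1, n):
            Gj = gmap.genes(mirnas[j])
            if not Gi or not Gj:
                continue
            num = sum(_best_match(net, g, Gj) for g in Gi)
            num += sum(_best_match(net, g, Gi) for g in Gj)
            S[i, j] = S[j, i] = num / (len(Gi) + len(Gj))
    return SimilarityMatrix(S, mirnas)


# ---------------------------------------------------------------------------
# interaction-profile features and similarity
# ---------------------------------------------------------------------------

def nndsvd(X: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD factors (W: n×d, H: d×m) of a nonnegative matrix.

    Per singular triplet the dominant-sign sections of the singular vectors
    are kept, scaled so that ``W @ H`` approximates ``X``; deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    n, m = X.shape
    if not 1 <= d <= min(n, m):
        raise ValueError(f"feature dimension d={d} outside [1, {min(n, m)}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((n, d))
    H = np.zeros((d, m))
    # leading pair: Perron vectors of a nonnegative matrix, sign-fixed
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for r in range(1, d):
        u, v = U[:, r], Vt[r, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sect_u, sect_v, norm = up, vp, n_up * n_vp
        else:
            sect_u, sect_v, norm = un, vn, n_un * n_vn
        if norm <= 0:
            continue  # component carries no same-sign mass
        scale = np.sqrt(s[r] * norm)
        W[:, r] = scale * sect_u / np.linalg.norm(sect_u)
        H[r, :] = scale * sect_v / np.linalg.norm(sect_v)
    return W, H


def default_feature_dim(shape: tuple[int, int]) -> int:
    """Default NNDSVD target dimension: min(50, 0.2·min(dims)), at least 1."""
    return max(1, min(50, int(0.2 * min(shape))))


def profile_features(Y: AssociationTensor, axis: str, d: int | None = None) -> FeatureMatrix:
    """Nonnegative low-dimensional interaction-profile features from Y.

    The miRNA (disease) profiles are the rows of the mode-1 (mode-2)
    unfolding; NNDSVD reduces them to ``d`` nonnegative components.
    """
    if axis == "mirna":
        M, ids = unfold(Y.values, 1), Y.mirna_ids
    elif axis == "disease":
        M, ids = unfold(Y.values, 2), Y.disease_ids
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    if d is None:
        d = default_feature_dim(M.shape)
        logger.info("profile_features(axis=%s): default feature dimension d=%d", axis, d)
    W, _ = nndsvd(M, d)
    return FeatureMatrix(W, ids)


def interaction_profile_similarity(
    F: FeatureMatrix,
    k_neighbors: int | None = None,
    bandwidth: float = 1.0,
) -> SimilarityMatrix:
    """Kernel neighborhood similarity of feature rows.

    Default backend: Gaussian kernel ``exp(-dist² / (2 h²))`` with bandwidth
    ``h`` = median pairwise distance × ``bandwidth``, restricted to each row's
    ``k_neighbors`` nearest neighbors (default 10% of n, at least 3),
    symmetrized by elementwise max, diagonal forced to 1.
    """
    X = F.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 entities")
    if k_neighbors is None:
        k_neighbors = max(3, int(0.1 * n))
    k_neighbors = min(k_neighbors, n - 1)
    D = squareform(pdist(X))
    med = np.median(D[np.triu_indices(n, k=1)])
    if med <= 0:
        logger.warning("constant feature rows: uniform similarity returned")
        return SimilarityMatrix(np.ones((n, n)), F.entity_ids)
    h = med * bandwidth
    Kmat = np.exp(-(D ** 2) / (2.0 * h * h))
    # keep each row's k nearest neighbors (smallest distances, self excluded)
    mask = np.zeros_like(Kmat, dtype=bool)
    for i in range(n):
        order = np.argsort(D[i])
        nn = [j for j in order if j != i][:k_neighbors]
        mask[i, nn] = True
    S = np.where(mask, Kmat, 0.0)
    S = np.maximum(S, S.T)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, F.entity_ids)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse_similarities(
    S_a: SimilarityMatrix,
    S_b: SimilarityMatrix,
    weights: tuple[float, float] = (0.5, 0.5),
) -> SimilarityMatrix:
    """Fuse two similarity sources over the same registry.

    Default backend: convex combination with the given weights, followed by
    re-symmetrization and a unit diagonal.  Alternative fusion schemes can be
    swapped in by callers; every backend must preserve the SimilarityMatrix
    contract.
    """
    if S_a.entity_ids != S_b.entity_ids:
        offending = [
            (a, b) for a, b in zip(S_a.entity_ids, S_b.entity_ids) if a != b
        ]
        extra = set(S_a.entity_ids) ^ set(S_b.entity_ids)
        raise ValueError(
            f"similarity registries differ: mismatched positions {offending[:5]}, "
            f"symmetric difference {sorted(extra)[:5]}"
        )
    wa, wb = float(weights[0]), float(weights[1])
    if wa < 0 or wb < 0 or wa + wb <= 0:
        raise ValueError("fusion weights must be nonnegative with positive sum")
    wa, wb = wa / (wa + wb), wb / (wa + wb)
    V = wa * S_a.values + wb * S_b.values
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 1.0)
    return SimilarityMatrix(np.clip(V, 0.0, 1.0), S_a.entity_ids)
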