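"""Cross-validation protocols and ranking metrics.

Two 5-fold protocols evaluate complementary abilities:

* ``type`` CV partitions the miRNA-disease *pairs* that have at least one
  known type; all type entries of a test pair are masked during training and
  the model must rank the correct type(s) first (Top-1 precision/recall/F1).
* ``triplet`` CV partitions the known *triples*; masked triples must be
  recovered among sampled unknown negatives (AUPR / AUC / F1, averaged over
  repeated negative-sampling seeds).

`hit_rate` measures the fraction of known triples recovered in the top
``floor(rho * N)`` of a ranked candidate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .tensorops import AssociationTensor

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSpec",
    "split_cv_type",
    "split_cv_triplet",
    "mask_training_tensor",
    "top1_metrics",
    "triplet_metrics",
    "hit_rate",
    "MetricReport",
]


@dataclass
class FoldSpec:
    """5 disjoint folds of pairs (type CV) or triples (triplet CV)."""

    mode: str  # "type" | "triplet"
    folds: list  # list of integer arrays, shape (n_f, 2) or (n_f, 3)
    seed: int

    def __post_init__(self):
        if self.mode not in ("type", "triplet"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")


@dataclass
class MetricReport:
    """Container for CV metrics; unused fields stay None."""

    top1_precision: float | None = None
    top1_recall: float | None = None
    top1_f1: float | None = None
    aupr: float | None = None
    auc: float | None = None
    f1: float | None = None
    per_seed: list | None = None
    hit_rates: dict | None = None


def _partition(n_items: int, seed: int, n_folds: int = 5) -> list:
    """Seeded near-equal partition of ``range(n_items)`` into index arrays."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def split_cv_type(Y: AssociationTensor, seed: int, n_folds: int = 5) -> FoldSpec:
    """Partition miRNA-disease pairs with >= 1 known type into 5 folds."""
    pairs = np.argwhere(Y.values.any(axis=2))  # (n, 2)
    if len(pairs) < n_folds:
        raise ValueError(
            f"need >= {n_folds} eligible pairs, found {len(pairs)}"
        )
    idx_folds = _partition(len(pairs), seed, n_folds)
    return FoldSpec("type", [pairs[f] for f in idx_folds], seed)


def split_cv_triplet(Y: AssociationTensor, seed: int, n_folds: int = 5) -> FoldSpec:
    """Partition the known triples into 5 folds."""
    triples = np.argwhere(Y.values == 1)  # (n, 3)
    if len(triples) < n_folds:
        raise ValueError(
            f"need >= {n_folds} known triples, found {len(triples)}"
        )
    idx_folds = _partition(len(triples), seed, n_folds)
    return FoldSpec("triplet", [triples[f] for f in idx_folds], seed)


def mask_training_tensor(Y: AssociationTensor, spec: FoldSpec, fold: int) -> AssociationTensor:
    """Training copy of Y with the test fold's entries zeroed.

    Type CV masks *all* type entries of each test pair; triplet CV zeroes only
    the test triples.
    """
    Yt = Y.copy()
    test = spec.folds[fold]
    if spec.mode == "type":
        Yt.values[test[:, 0], test[:, 1], :] = 0.0
    else:
        Yt.values[test[:, 0], test[:, 1], test[:, 2]] = 0.0
    return Yt


def top1_metrics(P: np.ndarray, truth: AssociationTensor, test_pairs: np.ndarray) -> MetricReport:
    """Top-1 precision / recall / F1 over test pairs.

    For each pair the single highest-scoring type (ties -> lowest type index)
    is compared with the pair's true type set: precision@1 is the hit
    indicator, recall@1 the hit divided by the number of true types, and F1
    their harmonic mean (0 when both are 0).  Pairs without any true type are
    excluded with a warning.
    """
    precs, recs, f1s = [], [], []
    skipped = 0
    for i, j in np.asarray(test_pairs):
        true_types = np.flatnonzero(truth.values[i, j, :] == 1)
        if len(true_types) == 0:
            skipped += 1
            continue
        t_hat = int(np.argmax(P[i, j, :]))  # argmax takes the lowest tied index
        hit = float(t_hat in true_types)
        prec = hit
        rec = hit / len(true_types)
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    if skipped:
        logger.warning("top1_metrics: excluded %d pairs without true types", skipped)
    if not precs:
        raise ValueError("no test pair has a true type")
    return MetricReport(
        top1_precision=float(np.mean(precs)),
        top1_recall=float(np.mean(recs)),
        top1_f1=float(np.mean(f1s)),
    )


def _pr_curve_metrics(y_true: np.ndarray, scores: np.ndarray):
    """(AUPR by trapezoid, max F1 along the PR curve)."""
    prec, rec, _ = precision_recall_curve(y_true, scores)
    # returned with decreasing recall; reverse (not sort) to keep the curve's
    # own ordering at recall ties
    aupr = float(np.trapezoid(prec[::-1], rec[::-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * prec * rec / (prec + rec)
    f1 = np.nan_to_num(f1)
    return aupr, float(np.max(f1))


def triplet_metrics(
    P: np.ndarray,
    truth: AssociationTensor,
    test_triples: np.ndarray,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> MetricReport:
    """AUPR / AUC / max-F1 with repeated balanced negative sampling.

    For each of ``n_seeds`` seeds, as many unknown triples as there are test
    positives are drawn uniformly without replacement as negatives; metrics
    are computed per seed and averaged.
    """
    test_triples = np.asarray(test_triples)
    if len(test_triples) == 0:
        raise ValueError("empty test-triple set")
    unknown = np.argwhere(truth.values == 0)
    if len(unknown) < len(test_triples):
        raise ValueError(
            f"insufficient unknown triples ({len(unknown)}) to match "
            f"{len(test_triples)} positives"
        )
    pos_scores = P[test_triples[:, 0], test_triples[:, 1], test_triples[:, 2]]
    per_seed = []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        pick = rng.choice(len(unknown), size=len(test_triples), replace=False)
        neg = unknown[pick]
        neg_scores = P[neg[:, 0], neg[:, 1], neg[:, 2]]
        scores = np.concatenate([pos_scores, neg_scores])
        y = np.concatenate(
            [np.ones(len(pos_scores)), np.zeros(len(neg_scores))]
        )
        auc = float(roc_auc_score(y, scores))
        aupr, f1 = _pr_curve_metrics(y, scores)
        per_seed.append({"seed": base_seed + s, "aupr": aupr, "auc": auc, "f1": f1})
    return MetricReport(
        aupr=float(np.mean([d["aupr"] for d in per_seed])),
        auc=float(np.mean([d["auc"] for d in per_seed])),
        f1=float(np.mean([d["f1"] for d in per_seed])),
        per_seed=per_seed,
    )


def hit_rate(scores: np.ndarray, known: np.ndarray, rho: float) -> float:
    """Fraction of known candidates inside the top ``floor(rho * N)``.

    ``scores`` ranks all N candidates; ``known`` is a boolean mask (or index
    array) marking the true subset.  Ties are broken by stable candidate
    order.
    """
    scores = np.asarray(scores, dtype=float)
    N = len(scores)
    known_mask = np.zeros(N, dtype=bool)
    known = np.asarray(known)
    if known.dtype == bool:
        if known.shape != scores.shape:
            raise ValueError("boolean known mask must match scores shape")
        known_mask = known
    else:
        known_mask[known] = True
    n_known = int(known_mask.sum())
    if n_known == 0:
        raise ValueError("hit_rate undefined for an empty known set")
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    top = int(np.floor(rho * N))
    # stable sort on negated scores: ties keep original candidate order
    order = np.argsort(-scores, kind="stable")
    hits = int(known_mask[order[:top]].sum())
    return hits / n_known
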