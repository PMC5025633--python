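"""Ensembled clustering for high-dimensional categorical data.

When J >> n, each base clustering is computed on a random subspace of the
variables. A subspace is drawn by bootstrap-with-deduplication: J draws
with replacement from {1..J}, keeping the distinct indices (expected size
~ 0.632 J). Repeating the step on the retained set gives the double (or
triple) bootstrap, shrinking the subspace further when J is very large.
Every variable has the same inclusion probability, and subspace dimensions
vary across draws, which is the source of ensemble diversity here: unlike
the low-dimensional algorithm, each base clustering recomputes its own
Hamming matrix and tree on its subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .agglom import ClusteringResult, agglomerate, cut_many
from .ensemble import (
    EnsembleResult,
    build_incidence,
    default_kmax,
    draw_cluster_counts,
    ensemble_dissimilarity,
)
from .hamming import hamming_matrix
from .io import CategoricalMatrix, ValidationError


@dataclass(frozen=True)
class SubspaceDraw:
    """A set of distinct, sorted column indices drawn from 1..J (0-based)."""

    indices: tuple
    level: int
    source_J: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size < 1 or idx.size > self.source_J:
            raise ValidationError("subspace size must lie in [1, J]")
        if len(np.unique(idx)) != idx.size:
            raise ValidationError("subspace indices must be distinct")
        if idx.min() < 0 or idx.max() >= self.source_J:
            raise ValidationError("subspace indices out of range")

    @property
    def size(self) -> int:
        return len(self.indices)


def bootstrap_subspace(J: int, level: int = 1, rng=None) -> SubspaceDraw:
    """Draw a random variable subspace by repeated bootstrap-deduplication.

    Level 1 takes J draws with replacement from {1..J} and keeps the
    distinct values; each additional level repeats the step on the set
    retained so far (J* draws from the J* kept indices).
    """
    if J < 1:
        raise ValidationError("J must be >= 1")
    if level < 1:
        raise ValidationError("bootstrap level must be >= 1")
    rng = as_rng(rng)
    kept = np.arange(J)
    for _ in range(level):
        kept = np.unique(rng.choice(kept, size=len(kept), replace=True))
    return SubspaceDraw(tuple(int(i) for i in kept), level, J)


def ensemble_cluster_highdim(
    X: CategoricalMatrix,
    B: int = 100,
    kmin: int = 2,
    kmax: int | None = None,
    level: int = 2,
    linkage: str = "average",
    policy: str = "pairwise_complete",
    rng=None,
) -> EnsembleResult:
    """Random-subspace ensembled clustering.

    For each of the B iterations: draw a subspace, compute the Hamming
    matrix restricted to it, agglomerate, and cut at K_b ~ DUnif(kmin,
    kmax). The K_b sequence is drawn first, then one subspace per
    iteration, so the draw order is well-defined for reproducibility.
    """
    rng = as_rng(rng)
    n = X.n
    if kmax is None:
        kmax = default_kmax(n)
    if kmax >= n:
        raise ValidationError(f"kmax must be < n, got kmax={kmax}, n={n}")
    ks = draw_cluster_counts(B, kmin, kmax, rng)
    clusterings = []
    subspace_sizes = []
    for b in range(B):
        draw = bootstrap_subspace(X.J, level, rng)
        subspace_sizes.append(draw.size)
        Xs = X.take_columns(np.asarray(draw.indices))
        D_b = hamming_matrix(Xs, policy)
        tree_b = agglomerate(D_b, linkage)
        k = int(ks[b])
        labels = cut_many(tree_b, [k])[k]
        clusterings.append(ClusteringResult(labels, k, {"linkage": linkage, "K": k, "subspace": draw.size}))
    incidence = build_incidence(clusterings, row_labels=list(X.row_labels))
    T = ensemble_dissimilarity(incidence)
    final_tree = agglomerate(T, linkage)
    config = {
        "B": B,
        "kmin": kmin,
        "kmax": kmax,
        "level": level,
        "linkage": linkage,
        "policy": policy,
        "mode": "highdim",
        "mean_subspace_size": float(np.mean(subspace_sizes)),
    }
    return EnsembleResult(T, incidence, final_tree, config)
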