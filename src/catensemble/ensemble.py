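"""Ensembled hierarchical clustering for low-dimensional categorical data.

B base clusterings — cuts of one Hamming-average-linkage tree at random
sizes K_b ~ DUnif(kmin, kmax) — are collected into an n x B incidence
matrix I whose (i, b) entry is the cluster index of observation i in base
clustering b. The ensembled dissimilarity T is the normalized Hamming
distance between rows of I: the fraction of base clusterings that separate
each pair. A final agglomeration on T gives the ensembled dendrogram, whose
longer lifetimes make the cluster structure easier to read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .agglom import ClusteringResult, Dendrogram, agglomerate, cut_many
from .hamming import DissimilarityMatrix, hamming_matrix
from .io import CategoricalMatrix, ValidationError


@dataclass
class IncidenceMatrix:
    """n x B matrix of base-clustering memberships; column b uses labels 1..K_b."""

    entries: np.ndarray
    ks: np.ndarray
    row_labels: list[str] | None = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int64)
        self.ks = np.asarray(self.ks, dtype=np.int64)
        if self.entries.ndim != 2:
            raise ValidationError("incidence matrix must be 2-D")
        if self.ks.shape != (self.entries.shape[1],):
            raise ValidationError("one K_b per column required")
        for b in range(self.entries.shape[1]):
            col = self.entries[:, b]
            if not np.array_equal(np.unique(col), np.arange(1, self.ks[b] + 1)):
                raise ValidationError(f"column {b} must use every label 1..K_b")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def B(self) -> int:
        return self.entries.shape[1]


@dataclass
class EnsembleResult:
    """Output of ensembled clustering: T, the incidence matrix and final tree."""

    T: DissimilarityMatrix
    incidence: IncidenceMatrix
    final_tree: Dendrogram
    config: dict = field(default_factory=dict)
    base_tree: Dendrogram | None = None


def default_kmax(n: int) -> int:
    """Ceiling-of-sqrt(n) heuristic for the largest base-clustering size.

    Chosen so the base clusterings range up to roughly the square root of
    the sample size (e.g. n=53 -> 8); clamped to [2, n].
    """
    if n < 4:
        raise ValidationError("default_kmax requires n >= 4")
    return min(max(2, math.ceil(math.sqrt(n))), n)


def draw_cluster_counts(B: int, kmin: int, kmax: int, rng) -> np.ndarray:
    """B i.i.d. draws of K_b from the discrete uniform on {kmin, ..., kmax}."""
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not 2 <= kmin <= kmax:
        raise ValidationError(f"need 2 <= kmin <= kmax, got kmin={kmin}, kmax={kmax}")
    rng = as_rng(rng)
    return rng.integers(kmin, kmax + 1, size=B).astype(np.int64)


def build_incidence(clusterings: list[ClusteringResult], row_labels=None) -> IncidenceMatrix:
    """Stack cluster assignments column-wise into the incidence matrix I."""
    if not clusterings:
        raise ValidationError("need at least one base clustering")
    n = len(clusterings[0].labels)
    for c in clusterings:
        if len(c.labels) != n:
            raise ValidationError("all base clusterings must cover the same observations")
    entries = np.column_stack([c.labels for c in clusterings])
    ks = np.array([c.K for c in clusterings], dtype=np.int64)
    return IncidenceMatrix(entries, ks, row_labels)


# row-block size for the O(n^2 B) comparison loop
_BLOCK_ELEMS = 4_000_000


def ensemble_dissimilarity(I: IncidenceMatrix) -> DissimilarityMatrix:
    """T[i, j] = fraction of base clusterings that place i and j apart."""
    E = I.entries
    n, B = E.shape
    diff = np.zeros((n, n), dtype=np.int64)
    block = max(1, _BLOCK_ELEMS // (max(n, 1) * max(B, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        diff[start:stop] = (E[start:stop, None, :] != E[None, :, :]).sum(axis=2)
    values = diff / B
    np.fill_diagonal(values, 0.0)
    labels = I.row_labels if I.row_labels is not None else [f"row{i + 1}" for i in range(n)]
    return DissimilarityMatrix(values, list(labels))


def ensemble_cluster(
    X: CategoricalMatrix,
    B: int = 200,
    kmin: int = 2,
    kmax: int | None = None,
    linkage: str = "average",
    policy: str = "pairwise_complete",
    rng=None,
) -> EnsembleResult:
    """Low-dimensional ensembled clustering.

    The base tree (Hamming distance + linkage) is computed once; the only
    stochastic element is the sequence of cut sizes K_b. Fully reproducible
    given an integer seed or seeded generator.
    """
    rng = as_rng(rng)
    n = X.n
    if kmax is None:
        kmax = default_kmax(n)
    if kmax >= n:
        raise ValidationError(f"kmax must be < n, got kmax={kmax}, n={n}")
    ks = draw_cluster_counts(B, kmin, kmax, rng)
    D = hamming_matrix(X, policy)
    base_tree = agglomerate(D, linkage)
    labels_by_k = cut_many(base_tree, np.unique(ks))
    clusterings = [
        ClusteringResult(labels_by_k[int(k)], int(k), {"linkage": linkage, "K": int(k)})
        for k in ks
    ]
    incidence = build_incidence(clusterings, row_labels=list(X.row_labels))
    T = ensemble_dissimilarity(incidence)
    final_tree = agglomerate(T, linkage)
    config = {
        "B": B,
        "kmin": kmin,
        "kmax": kmax,
        "linkage": linkage,
        "policy": policy,
        "mode": "lowdim",
    }
    return EnsembleResult(T, incidence, final_tree, config, base_tree)
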