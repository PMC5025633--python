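"""Agglomerative hierarchical clustering on a precomputed dissimilarity.

Supports average (default), complete and single linkage via Lance–Williams
updates. Normalized Hamming dissimilarities are multiples of 1/J, so tied
minimum distances are common; to make dendrograms bit-reproducible the
implementation always merges the tied pair whose (i, j) node ids are
lexicographically smallest, where a cluster's node id is the smallest
original observation index it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hamming import DissimilarityMatrix
from .io import ValidationError

LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering.

    ``merges`` holds n-1 rows ``(a, b, height, size)``: at each step the
    clusters represented by node ids ``a < b`` merge at the given height
    into a cluster of the given size, represented thereafter by ``a``.
    """

    merges: np.ndarray  # (n-1, 4): a, b, height, merged size
    leaf_labels: list[str]
    linkage: str = "average"

    def __post_init__(self):
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_labels)
        if self.merges.shape != (n - 1, 4):
            raise ValidationError("dendrogram must contain exactly n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusteringResult:
    """Flat cluster assignment with labels canonicalized by first occurrence."""

    labels: np.ndarray
    K: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValidationError("labels must use every cluster index 1..K")


def canonicalize_labels(raw) -> np.ndarray:
    """Renumber labels so cluster 1 contains observation 0, etc."""
    raw = np.asarray(raw)
    mapping: dict = {}
    out = np.empty(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def agglomerate(D: DissimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Build the merge tree of ``D`` under the requested linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    n = D.n
    if n < 2:
        raise ValidationError("need at least two observations to agglomerate")
    W = D.values.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    sizes = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4), dtype=float)
    for step in range(n - 1):
        # row-major scan over the symmetric matrix returns the
        # lexicographically smallest tied pair (i, j), i < j; ties are
        # detected with a 1e-12 band so that mathematically equal linkage
        # values (common on the 1/J Hamming grid) tie regardless of the
        # float summation order that produced them
        m = W.min()
        flat = int(np.argmax(W <= m + 1e-12))
        i, j = divmod(flat, n)
        h = W[i, j]
        sa, sb = sizes[i], sizes[j]
        merges[step] = (i, j, h, sa + sb)
        if linkage == "average":
            newrow = (sa * W[i] + sb * W[j]) / (sa + sb)
        elif linkage == "complete":
            newrow = np.maximum(W[i], W[j])
        else:
            newrow = np.minimum(W[i], W[j])
        W[i] = newrow
        W[:, i] = newrow
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
    return Dendrogram(merges, list(D.row_labels), linkage)


def _replay(tree: Dendrogram, wanted: set[int]) -> dict[int, np.ndarray]:
    """Apply merges in order, snapshotting the partition at each wanted K."""
    n = tree.n_leaves
    assign = np.arange(n)
    out: dict[int, np.ndarray] = {}
    if n in wanted:
        out[n] = canonicalize_labels(assign)
    for step in range(n - 1):
        a, b = int(tree.merges[step, 0]), int(tree.merges[step, 1])
        assign[assign == b] = a
        k = n - step - 1
        if k in wanted:
            out[k] = canonicalize_labels(assign)
    return out


def cut(tree: Dendrogram, K: int) -> ClusteringResult:
    """Partition obtained by undoing the last K-1 merges of the tree."""
    n = tree.n_leaves
    if not 1 <= K <= n:
        raise ValidationError(f"K must lie in [1, {n}], got {K}")
    labels = _replay(tree, {K})[K]
    return ClusteringResult(labels, K, {"linkage": tree.linkage, "K": K})


def cut_many(tree: Dendrogram, Ks) -> dict[int, np.ndarray]:
    """Labels for several cut sizes in a single pass over the merges."""
    ks = {int(k) for k in Ks}
    n = tree.n_leaves
    for k in ks:
        if not 1 <= k <= n:
            raise ValidationError(f"K must lie in [1, {n}], got {k}")
    return _replay(tree, ks)


def _sanitize(label: str) -> str:
    for ch in "(),:;[] \t'\"":
        label = label.replace(ch, "_")
    return label


def to_newick(tree: Dendrogram) -> str:
    """Newick serialization with branch lengths from merge heights.

    A leaf's branch length is the height of its parent merge; an internal
    node's is the difference between its parent's and its own height.
    """
    n = tree.n_leaves
    # node = (newick fragment without branch length, height of the node)
    nodes: dict[int, tuple[str, float]] = {
        i: (_sanitize(str(tree.leaf_labels[i])), 0.0) for i in range(n)
    }
    for step in range(n - 1):
        a, b = int(tree.merges[step, 0]), int(tree.merges[step, 1])
        h = float(tree.merges[step, 2])
        fa, ha = nodes[a]
        fb, hb = nodes.pop(b)
        frag = f"({fa}:{h - ha:.10g},{fb}:{h - hb:.10g})"
        nodes[a] = (frag, h)
    (frag, _), = nodes.values()
    return frag + ";"
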