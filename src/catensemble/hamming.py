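"""Normalized Hamming dissimilarity for categorical observations.

The dissimilarity between two coded vectors is the fraction of compared
positions at which they differ. Two missing-data policies are provided:

``pairwise_complete`` (default)
    Positions where either value is missing are excluded and the count of
    mismatches is renormalized by the number of jointly observed positions.
    A pair with no jointly observed position is assigned distance 1.0 (with
    a warning): maximally dissimilar rather than undefined, so downstream
    linkage stays well-posed.

``mismatch``
    A missing value matches nothing (including another missing value); the
    denominator is always J. Self-distance is 0 by definition.

Entries are exact integer-count ratios k/m up to float representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import CategoricalMatrix, ValidationError

logger = logging.getLogger(__name__)

POLICIES = ("pairwise_complete", "mismatch")

# row-block size for the O(n^2 J) comparison loops; bounds peak memory
_BLOCK_ELEMS = 4_000_000


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n dissimilarity with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    row_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if len(self.row_labels) != v.shape[0]:
            raise ValidationError("row_labels length does not match matrix size")
        if not np.array_equal(v, v.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.diagonal(v).any():
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("dissimilarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise ValueError(f"unknown missing-data policy {policy!r}; expected one of {POLICIES}")


def pairwise_hamming(x, y, x_missing=None, y_missing=None, policy: str = "pairwise_complete") -> float:
    """Normalized Hamming dissimilarity between two coded vectors."""
    _check_policy(policy)
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    xm = np.zeros(x.shape, bool) if x_missing is None else np.asarray(x_missing, bool)
    ym = np.zeros(y.shape, bool) if y_missing is None else np.asarray(y_missing, bool)
    both = ~xm & ~ym
    if policy == "pairwise_complete":
        m = int(both.sum())
        if m == 0:
            warnings.warn("no jointly observed positions; returning distance 1.0", stacklevel=2)
            return 1.0
        k = int(((x != y) & both).sum())
        return k / m
    matches = int(((x == y) & both).sum())
    return (x.shape[0] - matches) / x.shape[0]


def hamming_matrix(X: CategoricalMatrix, policy: str = "pairwise_complete") -> DissimilarityMatrix:
    """All-pairs normalized Hamming dissimilarity of the rows of ``X``.

    Vectorized in row blocks; the result is entrywise identical to looping
    :func:`pairwise_hamming` over pairs.
    """
    _check_policy(policy)
    codes = X.codes
    obs = ~X.missing_mask
    n, j = codes.shape
    values = np.zeros((n, n), dtype=float)
    block = max(1, _BLOCK_ELEMS // (max(n, 1) * max(j, 1)))
    if policy == "pairwise_complete":
        obs_f = obs.astype(np.float64)
        both = obs_f @ obs_f.T  # jointly observed counts
        diff = np.zeros((n, n), dtype=np.int64)
        for start in range(0, n, block):
            stop = min(start + block, n)
            neq = codes[start:stop, None, :] != codes[None, :, :]
            neq &= obs[start:stop, None, :]
            neq &= obs[None, :, :]
            diff[start:stop] = neq.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(both > 0, diff / np.maximum(both, 1), 1.0)
        degenerate = (both == 0) & ~np.eye(n, dtype=bool)
        if degenerate.any():
            logger.warning(
                "%d pairs share no observed positions; their distance is set to 1.0",
                int(degenerate.sum()) // 2,
            )
            warnings.warn("pairs with no jointly observed positions set to distance 1.0", stacklevel=2)
    else:
        match = np.zeros((n, n), dtype=np.int64)
        for start in range(0, n, block):
            stop = min(start + block, n)
            eq = codes[start:stop, None, :] == codes[None, :, :]
            eq &= obs[start:stop, None, :]
            eq &= obs[None, :, :]
            match[start:stop] = eq.sum(axis=2)
        values = (j - match) / j
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values, list(X.row_labels))
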