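"""Bootstrap cluster-stability assessment.

A clustering at size K is stable when reclustering bootstrap resamples
reproduces its clusters. For each reference cluster C the resample score is
the maximum Jaccard coefficient |A∩D| / |A∪D| between A = C restricted to
the resampled rows and any cluster D of the reclustered resample. Scores
near 1 across resamples indicate a reproducible cluster; the pooled median
per K summarizes a method's stability. The adjusted Rand index is provided
as an alternative partition-agreement measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ._rng import as_rng
from .agglom import ClusteringResult, agglomerate, cut
from .baselines import kmodes
from .ensemble import ensemble_cluster
from .hamming import hamming_matrix
from .highdim import ensemble_cluster_highdim
from .io import CategoricalMatrix, ValidationError

logger = logging.getLogger(__name__)


def jaccard_index(A, B) -> float:
    """|A∩B| / |A∪B| for two clusters viewed as sets of observation ids."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise ValidationError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(union)


def adjusted_rand(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    la = a.labels if isinstance(a, ClusteringResult) else np.asarray(a)
    lb = b.labels if isinstance(b, ClusteringResult) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValidationError("partitions must cover the same observations")
    return float(adjusted_rand_score(la, lb))


def _hier(X: CategoricalMatrix, K: int, rng, *, linkage="average", policy="pairwise_complete"):
    tree = agglomerate(hamming_matrix(X, policy), linkage)
    return cut(tree, K).labels


def _ensemble(X: CategoricalMatrix, K: int, rng, *, B=200, kmin=2, kmax=None,
              linkage="average", policy="pairwise_complete"):
    res = ensemble_cluster(X, B=B, kmin=kmin, kmax=kmax, linkage=linkage, policy=policy, rng=rng)
    return cut(res.final_tree, K).labels


def _ensemble_hi(X: CategoricalMatrix, K: int, rng, *, B=100, kmin=2, kmax=None, level=2,
                 linkage="average", policy="pairwise_complete"):
    res = ensemble_cluster_highdim(X, B=B, kmin=kmin, kmax=kmax, level=level,
                                   linkage=linkage, policy=policy, rng=rng)
    return cut(res.final_tree, K).labels


def _kmodes(X: CategoricalMatrix, K: int, rng, **kwargs):
    return kmodes(X, K, init="random", rng=rng, **kwargs).labels


METHODS = {
    "hier": _hier,
    "ensemble": _ensemble,
    "ensemble-hi": _ensemble_hi,
    "kmodes": _kmodes,
}


def resolve_method(method):
    """Accept a registry name or a callable ``(X, K, rng) -> labels``."""
    if callable(method):
        return method, getattr(method, "__name__", "custom")
    if method in METHODS:
        return METHODS[method], method
    raise ValueError(f"unknown clustering method {method!r}; expected one of {sorted(METHODS)} or a callable")


@dataclass
class StabilityReport:
    """Per-K, per-cluster bootstrap Jaccard coefficients for one method.

    ``per_k[K]`` is a (K, R_K) array: row c holds reference-cluster c's
    maximal Jaccard coefficient in each of the R_K effective resamples
    (resamples with fewer distinct rows than K are skipped and counted in
    ``skipped``).
    """

    method: str
    ks: tuple
    resamples: int
    per_k: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def pooled_median(self, K: int) -> float:
        """Median over all (cluster, resample) coefficients at size K."""
        return float(np.median(self.per_k[K]))

    def cluster_medians(self, K: int) -> np.ndarray:
        return np.median(self.per_k[K], axis=1)

    def pooled_mean(self, K: int) -> float:
        return float(np.mean(self.per_k[K]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: K, method, cluster, resample, jaccard."""
        rows = []
        for k in self.ks:
            arr = self.per_k[k]
            for c in range(arr.shape[0]):
                for r in range(arr.shape[1]):
                    rows.append((k, self.method, c + 1, r + 1, arr[c, r]))
        return pd.DataFrame(rows, columns=["K", "method", "cluster", "resample", "jaccard"])


def bootstrap_stability(
    X: CategoricalMatrix,
    method,
    Ks,
    resamples: int = 100,
    rng=None,
    method_kwargs: dict | None = None,
) -> StabilityReport:
    """Bootstrap Jaccard stability of ``method`` on ``X`` over cut sizes ``Ks``.

    For each K: cluster X at K to get the reference; then ``resamples``
    times, draw n rows with replacement, reduce to the distinct rows
    (duplicates are zero-distance under Hamming and would dominate
    linkage), recluster at K, and score every reference cluster by its best
    Jaccard match among the resample clusters.
    """
    fn, name = resolve_method(method)
    kwargs = method_kwargs or {}
    rng = as_rng(rng)
    n = X.n
    ks = tuple(int(k) for k in Ks)
    if resamples < 1:
        raise ValidationError("resamples must be >= 1")
    report = StabilityReport(name, ks, resamples, config=dict(kwargs))
    for K in ks:
        ref_labels = fn(X, K, rng, **kwargs)
        ref_clusters = [np.flatnonzero(ref_labels == c + 1) for c in range(K)]
        coeffs: list[np.ndarray] = []
        skipped = 0
        for _ in range(resamples):
            draw = rng.integers(0, n, size=n)
            S = np.unique(draw)
            if K > len(S):
                skipped += 1
                warnings.warn(f"resample with {len(S)} distinct rows skipped for K={K}", stacklevel=2)
                continue
            Xs = X.take_rows(S)
            sub_labels = fn(Xs, K, rng, **kwargs)
            k_sub = int(sub_labels.max())
            sub_clusters = [S[np.flatnonzero(sub_labels == c + 1)] for c in range(k_sub)]
            s_set = set(S.tolist())
            col = np.zeros(K)
            for ci, C in enumerate(ref_clusters):
                A = s_set.intersection(C.tolist())
                if not A:
                    col[ci] = 0.0
                    continue
                col[ci] = max(jaccard_index(A, D.tolist()) for D in sub_clusters)
            coeffs.append(col)
        if not coeffs:
            raise ValidationError(f"all resamples were skipped for K={K}")
        report.per_k[K] = np.column_stack(coeffs)
        report.skipped[K] = skipped
        if skipped:
            logger.warning("K=%d: skipped %d of %d resamples", K, skipped, resamples)
    return report


def compare_stability(report_e: StabilityReport, report_h: StabilityReport) -> pd.DataFrame:
    """Per-K pooled-median stability difference (first minus second report)."""
    if report_e.ks != report_h.ks:
        raise ValidationError("reports cover different K ranges")
    if report_e.resamples != report_h.resamples:
        raise ValidationError("reports use different resample counts")
    rows = []
    for k in report_e.ks:
        me = report_e.pooled_median(k)
        mh = report_h.pooled_median(k)
        rows.append((k, me, mh, me - mh))
    return pd.DataFrame(rows, columns=["K", "median_first", "median_second", "difference"])
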