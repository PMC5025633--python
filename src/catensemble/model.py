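"""Model-style front end.

``EnsembleClustering`` is constructed from data plus configuration and its
``fit`` returns an ``EnsembleClusteringResults`` carrying the ensembled
dissimilarity, the incidence matrix, the final dendrogram and a ``summary``.
``KModes`` wraps the baseline the same way. The functional layer in the
other modules remains available for scripted pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import as_rng
from .agglom import ClusteringResult, cut, to_newick
from .baselines import KModesResult, kmodes
from .ensemble import EnsembleResult, default_kmax, ensemble_cluster
from .highdim import ensemble_cluster_highdim
from .io import (
    AlphabetMap,
    CategoricalMatrix,
    DEFAULT_DNA_ALPHABET,
    read_aligned_fasta,
    read_categorical_table,
)


def _from_dataframe(df: pd.DataFrame) -> CategoricalMatrix:
    """First-appearance integer coding of a DataFrame of category labels."""
    n, j = df.shape
    codes = np.zeros((n, j), dtype=np.int64)
    missing = np.zeros((n, j), dtype=bool)
    code_maps = []
    for cidx, col in enumerate(df.columns):
        cmap: dict = {}
        vals = df[col].to_numpy()
        for ridx in range(n):
            v = vals[ridx]
            if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
                missing[ridx, cidx] = True
                continue
            key = str(v)
            if key not in cmap:
                cmap[key] = len(cmap) + 1
            codes[ridx, cidx] = cmap[key]
        code_maps.append(cmap)
    labels = [str(i) for i in df.index]
    cards = np.array([len(m) for m in code_maps])
    return CategoricalMatrix(codes, missing, labels, cards, code_maps)


class EnsembleClustering:
    """Ensembled hierarchical clustering model for categorical data.

    Parameters
    ----------
    data
        A :class:`CategoricalMatrix` (see the ``from_*`` constructors).
    B
        Ensemble size; defaults to 200 (low-dimensional) or 100 when a
        ``subspace_level`` is set.
    kmin, kmax
        Range of the DUnif(kmin, kmax) base-clustering sizes; ``kmax=None``
        uses the ceil-sqrt(n) heuristic.
    subspace_level
        ``None`` for the low-dimensional algorithm; 1, 2 or 3 selects the
        random-subspace algorithm with that bootstrap depth.
    """

    def __init__(
        self,
        data: CategoricalMatrix,
        B: int | None = None,
        kmin: int = 2,
        kmax: int | None = None,
        linkage: str = "average",
        policy: str = "pairwise_complete",
        subspace_level: int | None = None,
    ):
        self.data = data
        self.subspace_level = subspace_level
        self.B = B if B is not None else (100 if subspace_level else 200)
        self.kmin = kmin
        self.kmax = kmax
        self.linkage = linkage
        self.policy = policy

    @classmethod
    def from_csv(cls, path, delimiter: str = ",", header: bool = False, **kwargs):
        return cls(read_categorical_table(path, delimiter, header), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(_from_dataframe(df), **kwargs)

    @classmethod
    def from_fasta(cls, path, alphabet: AlphabetMap = DEFAULT_DNA_ALPHABET, **kwargs):
        kwargs.setdefault("subspace_level", 2)
        return cls(read_aligned_fasta(path, alphabet), **kwargs)

    def fit(self, seed=None) -> "EnsembleClusteringResults":
        rng = as_rng(seed)
        if self.subspace_level:
            res = ensemble_cluster_highdim(
                self.data, B=self.B, kmin=self.kmin, kmax=self.kmax,
                level=self.subspace_level, linkage=self.linkage,
                policy=self.policy, rng=rng,
            )
        else:
            res = ensemble_cluster(
                self.data, B=self.B, kmin=self.kmin, kmax=self.kmax,
                linkage=self.linkage, policy=self.policy, rng=rng,
            )
        return EnsembleClusteringResults(self, res, seed)


class EnsembleClusteringResults:
    """Fitted ensemble: dissimilarity, incidence, dendrogram, diagnostics."""

    def __init__(self, model: EnsembleClustering, result: EnsembleResult, seed):
        self.model = model
        self._result = result
        self.seed = seed

    @property
    def dissimilarity(self):
        return self._result.T

    @property
    def incidence(self):
        return self._result.incidence

    @property
    def tree(self):
        return self._result.final_tree

    @property
    def config(self) -> dict:
        return self._result.config

    def cut(self, K: int) -> ClusteringResult:
        return cut(self.tree, K)

    def to_newick(self) -> str:
        return to_newick(self.tree)

    def lifetimes(self, top: int = 5) -> pd.DataFrame:
        """Largest gaps between consecutive merge heights; long lifetimes
        suggest well-separated clusters and hint at a plausible K."""
        h = np.sort(self.tree.heights)
        gaps = np.diff(np.concatenate([h, [1.0]]))
        order = np.argsort(gaps)[::-1][:top]
        n = self.tree.n_leaves
        rows = [
            {"K": int(n - 1 - i), "height": float(h[i]), "lifetime": float(gaps[i])}
            for i in order
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.config
        n = self.model.data.n
        lines = [
            "Ensembled hierarchical clustering",
            "=" * 40,
            f"observations:        {n}",
            f"variables:           {self.model.data.J}",
            f"algorithm:           {'random-subspace' if cfg.get('mode') == 'highdim' else 'low-dimensional'}",
            f"ensemble size B:     {cfg['B']}",
            f"K_b ~ DUnif:         [{cfg['kmin']}, {cfg['kmax']}]",
            f"linkage:             {cfg['linkage']}",
            f"missing policy:      {cfg['policy']}",
        ]
        if cfg.get("mode") == "highdim":
            lines.append(f"bootstrap level:     {cfg['level']}")
            lines.append(f"mean subspace size:  {cfg['mean_subspace_size']:.1f}")
        lines.append(f"seed:                {self.seed}")
        lines.append("")
        lines.append("largest dendrogram lifetimes (candidate cluster counts):")
        lt = self.lifetimes()
        for _, row in lt.iterrows():
            lines.append(f"  K={int(row['K']):>3d}  height={row['height']:.4f}  lifetime={row['lifetime']:.4f}")
        return "\n".join(lines)


class KModes:
    """K-modes baseline in the same model/results idiom."""

    def __init__(self, data: CategoricalMatrix, k: int, init="random", max_iter: int = 100):
        self.data = data
        self.k = k
        self.init = init
        self.max_iter = max_iter

    @classmethod
    def from_csv(cls, path, k, delimiter: str = ",", header: bool = False, **kwargs):
        return cls(read_categorical_table(path, delimiter, header), k, **kwargs)

    def fit(self, seed=None) -> "KModesResults":
        rng = as_rng(seed)
        res = kmodes(self.data, self.k, init=self.init, rng=rng, max_iter=self.max_iter)
        return KModesResults(self, res, seed)


class KModesResults:
    def __init__(self, model: KModes, result: KModesResult, seed):
        self.model = model
        self._result = result
        self.seed = seed

    @property
    def labels(self):
        return self._result.labels

    @property
    def modes(self):
        return self._result.modes

    @property
    def cost(self):
        return self._result.cost

    def summary(self) -> str:
        r = self._result
        sizes = np.bincount(r.labels, minlength=self.model.k + 1)[1:]
        return "\n".join(
            [
                "K-modes clustering",
                "=" * 40,
                f"observations:   {self.model.data.n}",
                f"variables:      {self.model.data.J}",
                f"clusters k:     {self.model.k}",
                f"iterations:     {r.iterations} ({'converged' if r.converged else 'max_iter reached'})",
                f"objective:      {r.cost} within-cluster mismatches",
                f"cluster sizes:  {sizes.tolist()}",
                f"seed:           {self.seed}",
            ]
        )
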