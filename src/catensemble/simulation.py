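"""Multinomial-mixture data generator and factorial stability study.

Data are drawn from a mixture of product-multinomial distributions: given
its cluster, an observation's columns are independent categorical draws.
The full factorial design crosses

* sample size n in {100, 300, 1000},
* variable profile: ``mixed12`` (J=12: three binary, three ternary, four
  quaternary, two octonary columns) or ``quaternary100`` (J=100, all
  four-category),
* true cluster count K in {3, 5, 7},
* cluster balance: equal sizes, or sizes proportional to (1, 2, ..., K),
* separation: ``low`` (every category equally likely in every cluster, so
  clusters are indistinguishable) or ``high`` (each cluster concentrates
  probability 0.8 on a cluster-specific preferred category per column and
  spreads 0.2 over the rest),

giving 72 cells, 24 per sample size. The study runner scores hierarchical
and ensembled clustering on each cell by bootstrap Jaccard stability at
K in {3, 5, 7} and reports the pooled-median differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import as_rng
from .io import CategoricalMatrix, ValidationError
from .stability import bootstrap_stability, resolve_method

PROFILES = {
    "mixed12": (2, 2, 2, 3, 3, 3, 4, 4, 4, 4, 8, 8),
    "quaternary100": (4,) * 100,
}

#: concentration placed on a cluster's preferred category at high separation
P_HIGH = 0.8

_NS = (100, 300, 1000)
_KS = (3, 5, 7)
_BALANCES = ("equal", "unequal")
_SEPARATIONS = ("low", "high")


@dataclass(frozen=True)
class DesignPoint:
    n: int
    profile: str
    k_true: int
    balance: str
    separation: str

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown profile {self.profile!r}")
        if self.balance not in _BALANCES or self.separation not in _SEPARATIONS:
            raise ValidationError("invalid balance or separation level")
        if self.k_true < 2 or self.k_true > self.n:
            raise ValidationError("k_true must lie in [2, n]")

    @property
    def cardinalities(self) -> tuple:
        return PROFILES[self.profile]

    @property
    def J(self) -> int:
        return len(self.cardinalities)


@dataclass
class SyntheticDataset:
    X: CategoricalMatrix
    true_labels: np.ndarray
    design: DesignPoint
    probabilities: list  # per cluster: list of per-column probability vectors


def make_design(full: bool = True, ns=None) -> list[DesignPoint]:
    """The factorial design: 72 cells in full, or the 24 n=100 cells."""
    if ns is None:
        ns = _NS if full else (100,)
    cells = []
    for n, profile, k, balance, sep in itertools.product(
        ns, PROFILES, _KS, _BALANCES, _SEPARATIONS
    ):
        cells.append(DesignPoint(n, profile, k, balance, sep))
    return cells


def cluster_sizes(n: int, k: int, balance: str) -> np.ndarray:
    """Deterministic cluster sizes; remainders go to the first clusters."""
    if balance == "equal":
        base = np.full(k, n // k, dtype=np.int64)
    else:
        props = np.arange(1, k + 1) / (k * (k + 1) / 2)
        base = np.floor(n * props).astype(np.int64)
    rem = n - int(base.sum())
    base[:rem] += 1
    return base


def category_probabilities(design: DesignPoint) -> list:
    """Per-cluster, per-column category probability vectors.

    High separation: cluster c's preferred category in column j (both
    1-based) is 1 + ((c + j) mod m_j) and receives probability ``P_HIGH``;
    the remaining mass is uniform over the other categories. Low
    separation: uniform everywhere (no cluster signal at all).
    """
    out = []
    for c in range(1, design.k_true + 1):
        cols = []
        for j, m in enumerate(design.cardinalities, start=1):
            if design.separation == "low":
                p = np.full(m, 1.0 / m)
            else:
                p = np.full(m, (1.0 - P_HIGH) / (m - 1))
                p[(c + j) % m] = P_HIGH
            cols.append(p)
        out.append(cols)
    return out


def generate(design: DesignPoint, rng=None) -> SyntheticDataset:
    """Draw one dataset from the design cell's multinomial mixture."""
    rng = as_rng(rng)
    sizes = cluster_sizes(design.n, design.k_true, design.balance)
    probs = category_probabilities(design)
    labels = np.repeat(np.arange(1, design.k_true + 1), sizes)
    codes = np.zeros((design.n, design.J), dtype=np.int64)
    row = 0
    for c, size in enumerate(sizes):
        for j, m in enumerate(design.cardinalities):
            codes[row : row + size, j] = rng.choice(m, size=size, p=probs[c][j]) + 1
        row += size
    mask = np.zeros_like(codes, dtype=bool)
    row_labels = [f"obs{i + 1}" for i in range(design.n)]
    cards = np.array([len(np.unique(codes[:, j])) for j in range(design.J)])
    X = CategoricalMatrix(codes, mask, row_labels, cards)
    return SyntheticDataset(X, labels, design, probs)


@dataclass
class StudyResult:
    """Outputs of the factorial stability study."""

    table: pd.DataFrame          # cell x K x method pooled medians (long)
    differences: pd.DataFrame    # cell x K ensemble-minus-hierarchical medians
    mean_diff_by_n: pd.Series    # averaged over cells and K, grouped by n
    mean_diff_by_profile: pd.Series
    config: dict = field(default_factory=dict)

    @property
    def overall_mean_difference(self) -> float:
        return float(self.differences["difference"].mean())


def run_study(
    designs: list[DesignPoint],
    methods=("ensemble", "hier"),
    Ks=_KS,
    resamples: int = 100,
    rng=None,
    replicates: int = 1,
    method_kwargs: dict | None = None,
) -> StudyResult:
    """Score each design cell by bootstrap Jaccard stability per method.

    For every cell (and replicate), a dataset is generated and each method
    is assessed with :func:`bootstrap_stability` at every K in ``Ks``; the
    study table records the pooled median coefficients. When exactly two
    methods are given, differences are reported as first minus second.
    """
    rng = as_rng(rng)
    method_kwargs = method_kwargs or {}
    method_names = [resolve_method(m)[1] for m in methods]
    if len(set(method_names)) != len(method_names):
        raise ValidationError("methods must have distinct names")
    rows = []
    for cell_idx, design in enumerate(designs):
        for rep in range(replicates):
            cell_rng = rng.spawn(1)[0]
            data = generate(design, cell_rng)
            # paired design: every method sees the same generator state, so
            # bootstrap resamples are shared across methods within a cell
            state = cell_rng.bit_generator.state
            for method, mname in zip(methods, method_names):
                method_rng = np.random.default_rng()
                method_rng.bit_generator.state = state
                report = bootstrap_stability(
                    data.X, method, Ks, resamples=resamples, rng=method_rng,
                    method_kwargs=method_kwargs.get(mname, {}),
                )
                for K in Ks:
                    rows.append(
                        {
                            "cell": cell_idx,
                            "replicate": rep,
                            "n": design.n,
                            "profile": design.profile,
                            "J": design.J,
                            "k_true": design.k_true,
                            "balance": design.balance,
                            "separation": design.separation,
                            "K": K,
                            "method": mname,
                            "median_jaccard": report.pooled_median(K),
                            "mean_jaccard": report.pooled_mean(K),
                        }
                    )
    table = pd.DataFrame(rows)
    keys = ["cell", "replicate", "n", "profile", "J", "k_true", "balance", "separation", "K"]
    wide = table.pivot_table(index=keys, columns="method", values="median_jaccard").reset_index()
    if len(method_names) == 2:
        m0, m1 = method_names
        wide["difference"] = wide[m0] - wide[m1]
    else:
        wide["difference"] = np.nan
    by_n = wide.groupby("n")["difference"].mean()
    by_profile = wide.groupby("profile")["difference"].mean()
    return StudyResult(
        table,
        wide,
        by_n,
        by_profile,
        config={"methods": tuple(method_names), "Ks": tuple(Ks), "resamples": resamples, "replicates": replicates},
    )


def reduced_design(n: int = 100) -> list[DesignPoint]:
    """The 24 design cells at a single sample size."""
    return [replace(d, n=n) for d in make_design(full=False)]
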