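"""K-modes clustering for categorical data (comparison baseline).

Lloyd-style alternation with cluster modes as centers: each observation is
assigned to the mode with the fewest mismatches (counted over positions
where both the observation and the mode are non-missing), and each
cluster's mode is updated column-wise to the most frequent non-missing
code. The algorithm is sensitive to the initial modes, which is exactly why
the ensemble approach avoids mode-based centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .io import CategoricalMatrix, ValidationError


@dataclass
class KModesResult:
    labels: np.ndarray          # n entries in 1..k
    modes: np.ndarray           # k x J codes
    mode_mask: np.ndarray       # True where a mode cell is missing
    iterations: int
    cost: int                   # total within-cluster mismatches
    converged: bool
    cost_history: list          # objective after each assign+update sweep


def _mismatches(codes, mask, modes, mode_mask):
    """Mismatch counts of every row against every mode (n x k)."""
    both = ~mask[:, None, :] & ~mode_mask[None, :, :]
    neq = codes[:, None, :] != modes[None, :, :]
    return (neq & both).sum(axis=2)


def _update_mode(codes, mask, rows, j, current_code, current_missing):
    col = codes[rows, j]
    obs = col[~mask[rows, j]]
    if obs.size == 0:
        return current_code, current_missing
    vals, counts = np.unique(obs, return_counts=True)
    best = vals[counts == counts.max()].min()  # tie -> smallest code
    return int(best), False


def kmodes(
    X: CategoricalMatrix,
    k: int,
    init="random",
    rng=None,
    max_iter: int = 100,
) -> KModesResult:
    """K-modes clustering of ``X`` into ``k`` clusters.

    ``init`` is either ``"random"`` (k distinct rows chosen uniformly) or a
    list of k distinct row indices (0-based). Assignment ties go to the
    lowest cluster index; an emptied cluster is re-seeded with the
    observation farthest from its current mode.
    """
    n, J = X.n, X.J
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    rng = as_rng(rng)
    if isinstance(init, str) and init == "random":
        idx = rng.choice(n, size=k, replace=False)
    else:
        idx = np.asarray(list(init), dtype=np.intp)
        if len(np.unique(idx)) != k or len(idx) != k:
            raise ValidationError("init must give k distinct row indices")
        if idx.min() < 0 or idx.max() >= n:
            raise ValidationError("init row index out of range")
    codes, mask = X.codes, X.missing_mask
    modes = codes[idx].copy()
    mode_mask = mask[idx].copy()

    labels = np.zeros(n, dtype=np.int64)
    iterations = 0
    converged = False
    cost_history: list[int] = []
    for iterations in range(1, max_iter + 1):
        dist = _mismatches(codes, mask, modes, mode_mask)
        new_labels = dist.argmin(axis=1) + 1  # argmin ties -> lowest index
        # re-seed emptied clusters deterministically
        for c in range(k):
            if not (new_labels == c + 1).any():
                far = int(np.argmax(dist[:, c]))
                new_labels[far] = c + 1
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for c in range(k):
            rows = np.flatnonzero(labels == c + 1)
            for j in range(J):
                modes[c, j], mode_mask[c, j] = _update_mode(
                    codes, mask, rows, j, modes[c, j], mode_mask[c, j]
                )
        sweep_cost = _mismatches(codes, mask, modes, mode_mask)
        cost_history.append(int(sweep_cost[np.arange(n), labels - 1].sum()))
    dist = _mismatches(codes, mask, modes, mode_mask)
    cost = int(dist[np.arange(n), labels - 1].sum())
    return KModesResult(labels, modes, mode_mask, iterations, cost, converged, cost_history)
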