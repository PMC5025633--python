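import numpy as np
import pytest

from catensemble import (
    adjusted_rand,
    bootstrap_stability,
    compare_stability,
    jaccard_index,
)
from catensemble.io import ValidationError
from catensemble.stability import StabilityReport, resolve_method

from conftest import make_cat


def ari_from_contingency(a, b):
    """From-scratch Hubert-Arabie formula via the contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.sum((a == x) & (b == y))) for y in ub] for x in ua])
    comb2 = lambda v: v * (v - 1) / 2
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(1)).sum()
    sum_b = comb2(table.sum(0)).sum()
    n = len(a)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


def two_block_data(n_per=20, J=10):
    """Two maximally separated clusters: constant distinct rows."""
    codes = np.vstack(
        [np.ones((n_per, J), dtype=np.int64), np.full((n_per, J), 2, dtype=np.int64)]
    )
    return make_cat(codes)


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard_index({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_identical_sets(self):
        assert jaccard_index({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_index({1}, {2}) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_index(set(), set())


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_invariance(self):
        assert adjusted_rand([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_matches_contingency_formula(self, rng):
        for _ in range(10):
            a = rng.integers(1, 5, 50)
            b = rng.integers(1, 4, 50)
            assert adjusted_rand(a, b) == pytest.approx(ari_from_contingency(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand([1, 2], [1, 2, 3])


class TestBootstrapStability:
    def test_perfectly_separated_clusters_fully_stable(self, rng):
        X = two_block_data()
        rep = bootstrap_stability(X, "hier", [2], resamples=20, rng=rng)
        assert np.all(rep.per_k[2] == 1.0)

    def test_random_labeler_is_unstable(self, rng):
        def random_labels(X, K, r, **kw):
            lab = r.integers(1, K + 1, X.n)
            lab[:K] = np.arange(1, K + 1)
            return lab

        X = two_block_data(20, 6)  # n=40
        rep = bootstrap_stability(X, random_labels, [2], resamples=30, rng=rng)
        med = np.median(rep.per_k[2])
        assert med < 0.8
        # permutation oracle: null distribution of the max-Jaccard score for
        # random bipartitions of 40 items, evaluated on 5-resample batches
        null_rng = np.random.default_rng(4242)
        null_meds = []
        for _ in range(400):
            batch = []
            for _ in range(5):
                ref = null_rng.integers(0, 2, 40)
                sub = null_rng.integers(0, 2, 40)
                for c in (0, 1):
                    A = set(np.flatnonzero(ref == c).tolist())
                    best = max(
                        jaccard_index(A, set(np.flatnonzero(sub == d).tolist()))
                        for d in (0, 1)
                        if A or (sub == d).any()
                    )
                    batch.append(best)
            null_meds.append(np.median(batch))
        lo, hi = np.quantile(null_meds, [0.001, 0.999])
        rep5 = bootstrap_stability(X, random_labels, [2], resamples=5, rng=rng)
        assert lo - 0.15 <= np.median(rep5.per_k[2]) <= hi + 0.15

    def test_seeded_determinism(self, rng):
        X = two_block_data(10, 5)
        r1 = bootstrap_stability(X, "hier", [2, 3], 10, np.random.default_rng(3))
        r2 = bootstrap_stability(X, "hier", [2, 3], 10, np.random.default_rng(3))
        for k in (2, 3):
            assert np.array_equal(r1.per_k[k], r2.per_k[k])

    def test_small_resamples_skipped_when_k_exceeds_distinct_rows(self, rng):
        codes = np.array([[1, 1], [1, 2], [2, 2], [2, 1]])
        X = make_cat(codes)
        with pytest.warns(UserWarning):
            rep = bootstrap_stability(X, "hier", [4], resamples=30, rng=rng)
        assert rep.skipped[4] > 0
        assert rep.per_k[4].shape[1] == 30 - rep.skipped[4]

    def test_long_frame_layout(self, rng):
        X = two_block_data(8, 4)
        rep = bootstrap_stability(X, "hier", [2, 3], resamples=6, rng=rng)
        df = rep.to_frame()
        assert list(df.columns) == ["K", "method", "cluster", "resample", "jaccard"]
        assert len(df) == 2 * 6 + 3 * 6
        assert df["jaccard"].between(0, 1).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            resolve_method("mystery")


class TestCompareStability:
    def _report(self, values_by_k, method="m"):
        rep = StabilityReport(method, tuple(values_by_k), 4)
        for k, v in values_by_k.items():
            rep.per_k[k] = np.asarray(v, dtype=float)
        return rep

    def test_identical_reports_give_zero(self):
        vals = {3: np.full((3, 4), 0.7), 5: np.full((5, 4), 0.6)}
        df = compare_stability(self._report(vals), self._report(vals))
        assert (df["difference"] == 0).all()

    def test_constant_gap(self):
        e = self._report({3: np.ones((3, 4))})
        h = self._report({3: np.full((3, 4), 0.5)})
        df = compare_stability(e, h)
        assert (df["difference"] == 0.5).all()

    def test_mismatched_ks_rejected(self):
        e = self._report({3: np.ones((3, 4))})
        h = self._report({4: np.ones((4, 4))})
        with pytest.raises(ValidationError):
            compare_stability(e, h)

    def test_ensemble_no_worse_on_structured_data(self, rng):
        # 3-cluster multinomial data: ensemble minus hierarchical median
        # difference is non-negative at the true K for most generator seeds
        from catensemble import DesignPoint, generate

        wins = 0
        trials = 8
        for s in range(trials):
            data = generate(DesignPoint(60, "mixed12", 3, "equal", "high"), np.random.default_rng(100 + s))
            re = bootstrap_stability(data.X, "ensemble", [3], 12, np.random.default_rng(s))
            rh = bootstrap_stability(data.X, "hier", [3], 12, np.random.default_rng(s))
            diff = compare_stability(re, rh)["difference"].iloc[0]
            wins += diff >= 0
        assert wins >= 0.7 * trials
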