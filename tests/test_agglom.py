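import numpy as np
import pytest

from catensemble import agglomerate, cut, cut_many, to_newick
from catensemble.agglom import Dendrogram, canonicalize_labels
from catensemble.hamming import DissimilarityMatrix
from catensemble.io import ValidationError


def dmat(values, labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"r{i}" for i in range(values.shape[0])]
    return DissimilarityMatrix(values, labels)


def brute_force_merges(D, linkage):
    """O(n^3) re-scan agglomerator recomputing every cluster distance from
    the original matrix at each step; lexicographic tie rule on the
    smallest-leaf representatives."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for _ in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                cross = [D[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    d = sum(cross) / len(cross)
                elif linkage == "complete":
                    d = max(cross)
                else:
                    d = min(cross)
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        merges.append((a, b, d, len(clusters[a])))
    return merges


def random_tied_matrix(rng, n, denom=8):
    """Random dissimilarity with distances on a coarse 1/denom grid (ties)."""
    v = rng.integers(1, denom + 1, size=(n, n)) / denom
    v = np.triu(v, 1)
    v = v + v.T
    return v


class TestAgglomerate:
    def three_point(self):
        return dmat([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]], ["a", "b", "c"])

    def test_average_linkage_heights(self):
        t = agglomerate(self.three_point(), "average")
        assert t.merges[0].tolist() == [0, 1, 0.1, 2]
        assert t.merges[1, 2] == pytest.approx(0.85)

    def test_complete_and_single_second_merge(self):
        assert agglomerate(self.three_point(), "complete").merges[1, 2] == pytest.approx(0.9)
        assert agglomerate(self.three_point(), "single").merges[1, 2] == pytest.approx(0.8)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_brute_force_rescan(self, rng, linkage):
        for trial in range(25):
            n = int(rng.integers(3, 13))
            v = random_tied_matrix(rng, n)
            tree = agglomerate(dmat(v), linkage)
            expect = brute_force_merges(v, linkage)
            for step, (a, b, d, size) in enumerate(expect):
                assert tree.merges[step, 0] == a
                assert tree.merges[step, 1] == b
                assert tree.merges[step, 2] == pytest.approx(d)
                assert tree.merges[step, 3] == size

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            v = random_tied_matrix(rng, 10)
            h = agglomerate(dmat(v), "average").heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_matches_scipy_on_tie_free_matrix(self, rng):
        scipy = pytest.importorskip("scipy")
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        v = rng.random((9, 9))
        v = np.triu(v, 1) / 2  # distinct with probability 1
        v = v + v.T
        ours = agglomerate(dmat(v), "average")
        Z = scipy_linkage(squareform(v), method="average")
        np.testing.assert_allclose(np.sort(ours.heights), np.sort(Z[:, 2]), atol=1e-12)

    def test_singleton_input_rejected(self):
        with pytest.raises(ValidationError):
            agglomerate(dmat(np.zeros((1, 1))))

    def test_permutation_equivariance(self, rng):
        v = rng.random((8, 8))
        v = np.triu(v, 1)
        v = v + v.T
        perm = rng.permutation(8)
        vp = v[np.ix_(perm, perm)]
        base = cut(agglomerate(dmat(v)), 3).labels
        permuted = cut(agglomerate(dmat(vp)), 3).labels
        assert np.array_equal(canonicalize_labels(base[perm]), permuted)

    def test_ultrametric_recovered_by_all_linkages(self):
        # two tight pairs joined at the root: an exactly ultrametric matrix
        v = np.array(
            [
                [0, 0.1, 0.9, 0.9],
                [0.1, 0, 0.9, 0.9],
                [0.9, 0.9, 0, 0.2],
                [0.9, 0.9, 0.2, 0],
            ]
        )
        for linkage in ("average", "complete", "single"):
            t = agglomerate(dmat(v), linkage)
            assert t.heights.tolist() == [0.1, 0.2, 0.9]
            assert cut(t, 2).labels.tolist() == [1, 1, 2, 2]


class TestCut:
    def test_extreme_cuts(self, rng):
        v = random_tied_matrix(rng, 6)
        t = agglomerate(dmat(v))
        assert np.array_equal(cut(t, 1).labels, np.ones(6, dtype=int))
        assert np.array_equal(cut(t, 6).labels, np.arange(1, 7))

    def test_three_point_two_clusters(self):
        t = agglomerate(dmat([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]]))
        assert cut(t, 2).labels.tolist() == [1, 1, 2]

    def test_out_of_range_rejected(self):
        t = agglomerate(dmat([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValidationError):
            cut(t, 3)

    def test_cut_many_agrees_with_single_cuts(self, rng):
        v = random_tied_matrix(rng, 10)
        t = agglomerate(dmat(v))
        many = cut_many(t, range(2, 7))
        for k in range(2, 7):
            assert np.array_equal(many[k], cut(t, k).labels)


class TestNewick:
    def test_pair_string(self):
        t = Dendrogram(np.array([[0, 1, 0.4, 2.0]]), ["a", "b"])
        assert to_newick(t) == "(a:0.4,b:0.4);"

    def test_three_point_cherry(self):
        t = agglomerate(dmat([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]], ["a", "b", "c"]))
        assert to_newick(t) == "((a:0.1,b:0.1):0.75,c:0.85);"

    def test_round_trip_topology(self, rng):
        dendropy = pytest.importorskip("dendropy")
        for _ in range(5):
            n = int(rng.integers(4, 10))
            v = rng.random((n, n))
            v = np.triu(v, 1)
            v = v + v.T
            labels = [f"t{i}" for i in range(n)]
            tree = agglomerate(dmat(v, labels))
            parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
            # same leaves, and the n-1 internal nodes survive parsing
            assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(labels)
            internal = [nd for nd in parsed if not nd.is_leaf()]
            assert len(internal) == n - 1
            # cophenetic distance of the first merged pair equals twice its height
            a, b = int(tree.merges[0, 0]), int(tree.merges[0, 1])
            pdm = parsed.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in parsed.taxon_namespace}
            d = pdm.distance(taxa[labels[a]], taxa[labels[b]])
            assert d == pytest.approx(2 * tree.merges[0, 2], abs=1e-9)
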