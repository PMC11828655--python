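"""Standardization, Euclidean distances, UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import lattiq as lq
from lattiq.diversity import DistanceMatrix, _upgma_merges
from lattiq.errors import StandardizationError, LattiqError


def naive_upgma(D):
    """O(n^3) re-scan oracle: recompute all average linkages from raw
    distances at every step (no Lance-Williams update)."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    node_id = {i: i for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = np.mean([D[p, q] for p in clusters[a] for q in clusters[b]])
                lo, hi = sorted((min(clusters[a]), min(clusters[b])))
                key = (d, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d = best[0][0]
        merges.append(
            (min(node_id[a], node_id[b]), max(node_id[a], node_id[b]), d,
             len(clusters[a]) + len(clusters[b]))
        )
        clusters[a] = clusters[a] + clusters[b]
        node_id[a] = nxt
        del clusters[b]
        nxt += 1
    return np.array(merges)


def random_distance_matrix(n, rng):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d


class TestStandardizeAndDistance:
    def test_identical_accessions_give_zero_distance(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 3.0, 5.0]})
        _, D = lq.standardize_and_distance(m)
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_in_all_traits_closed_form(self):
        # two profiles differing by exactly 1 sd in each of 11 traits
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(6, 11)))
        z = (z - z.mean()) / z.std(ddof=1)
        d = np.sqrt(((z.iloc[0] - z.iloc[1]) ** 2).sum())
        shifted = z.iloc[0] - (z.iloc[0] - z.iloc[1]) / d  # unit step towards row 1
        assert np.sqrt(((z.iloc[0] - shifted) ** 2).sum()) == pytest.approx(1.0)
        # and the pure closed form: profiles offset by 1 in all 11 traits
        a = np.zeros(11)
        b = np.ones(11)
        assert np.linalg.norm(a - b) == pytest.approx(np.sqrt(11), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        z, D = lq.standardize_and_distance(m)
        zz = z.to_numpy()
        for i in range(6):
            for j in range(6):
                want = np.sqrt(((zz[i] - zz[j]) ** 2).sum())
                assert D.values[i, j] == pytest.approx(want, abs=1e-10)

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(8, 3)))
        z1 = lq.diversity.standardize(m)
        z2 = lq.diversity.standardize(z1)
        assert np.allclose(z1, z2, atol=1e-10)

    def test_zero_variance_trait_named_in_error(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(StandardizationError, match="flat"):
            lq.standardize_and_distance(m)

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        _, D = lq.standardize_and_distance(m)
        idx = rng.integers(0, 10, size=(30, 3))
        for a, b, c in idx:
            assert D.values[a, c] <= D.values[a, b] + D.values[b, c] + 1e-9


class TestDistanceSummary:
    def test_equilateral_configuration(self):
        d = 3.0
        vals = np.full((4, 4), d)
        np.fill_diagonal(vals, 0.0)
        out = lq.distance_summary(DistanceMatrix(ids=tuple("wxyz"), values=vals))
        row = out.loc["w"]
        assert row["mean"] == d and row["sd"] == 0 and row["cv_percent"] == 0

    def test_three_point_arithmetic(self):
        vals = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.0]])
        out = lq.distance_summary(DistanceMatrix(ids=("a", "b", "c"), values=vals))
        assert out.loc["overall", "mean"] == pytest.approx(4.0)
        assert out.loc["overall", "min"] == 2 and out.loc["overall", "max"] == 6

    def test_pair_count_for_49_accessions(self):
        rng = np.random.default_rng(4)
        d = random_distance_matrix(49, rng)
        D = DistanceMatrix(ids=tuple(range(49)), values=d)
        iu = np.triu_indices(49, k=1)
        assert len(d[iu]) == 1176  # 49 * 48 / 2 unique pairs feed the overall row
        out = lq.distance_summary(D)
        assert out.loc["overall", "mean"] == pytest.approx(d[iu].mean())

    def test_too_few_accessions(self):
        vals = np.array([[0, 1], [1, 0.0]])
        with pytest.raises(LattiqError):
            lq.distance_summary(DistanceMatrix(ids=("a", "b"), values=vals))


class TestUPGMA:
    def test_two_leaves_single_merge(self):
        vals = np.array([[0, 3.0], [3.0, 0]])
        dendro, clus, nwk = lq.upgma_cluster(
            DistanceMatrix(ids=("a", "b"), values=vals), K=1
        )
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(3.0)
        assert nwk == "(a:1.5,b:1.5);"

    def test_three_point_hand_agglomeration(self):
        vals = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.0]])
        D = DistanceMatrix(ids=("A", "B", "C"), values=vals)
        dendro, clus, _ = lq.upgma_cluster(D, K=2)
        assert dendro.merges[0, 2] == pytest.approx(2.0)  # {A,B} first
        assert dendro.merges[1, 2] == pytest.approx(5.0)  # (4 + 6) / 2 with C
        assert clus.labels.to_dict() == {"A": 1, "B": 1, "C": 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_list_equals_naive_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = random_distance_matrix(8, rng)
        got = _upgma_merges(d)
        want = naive_upgma(d)
        assert np.allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_average_linkage(self, seed):
        """Independent cross-check: merge heights and sizes match scipy's
        UPGMA on tie-free random matrices."""
        rng = np.random.default_rng(100 + seed)
        d = random_distance_matrix(12, rng)
        got = _upgma_merges(d)
        want = linkage(squareform(d), method="average")
        assert np.allclose(np.sort(got[:, 2]), np.sort(want[:, 2]), atol=1e-8)
        assert np.allclose(got[:, 2], want[:, 2], atol=1e-8)

    def test_heights_monotone_and_ultrametric(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(15, rng)
        D = DistanceMatrix(ids=tuple(range(15)), values=d)
        dendro, _, _ = lq.upgma_cluster(D, K=3)
        h = dendro.heights
        assert (np.diff(h) >= -1e-12).all()

    def test_relabeling_permutes_not_changes(self):
        rng = np.random.default_rng(10)
        d = random_distance_matrix(9, rng)
        perm = rng.permutation(9)
        D1 = DistanceMatrix(ids=tuple(range(9)), values=d)
        D2 = DistanceMatrix(ids=tuple(perm), values=d[np.ix_(perm, perm)])
        _, c1, _ = lq.upgma_cluster(D1, K=3)
        _, c2, _ = lq.upgma_cluster(D2, K=3)
        # same partition of ids, possibly different cluster numbers
        part1 = {frozenset(m) for m in c1.members.values()}
        part2 = {frozenset(m) for m in c2.members.values()}
        assert part1 == part2

    def test_k_extremes(self):
        rng = np.random.default_rng(11)
        d = random_distance_matrix(6, rng)
        D = DistanceMatrix(ids=tuple("abcdef"), values=d)
        _, c_all, _ = lq.upgma_cluster(D, K=6)
        assert sorted(c_all.labels) == [1, 2, 3, 4, 5, 6]  # all singletons
        _, c_one, _ = lq.upgma_cluster(D, K=1)
        assert set(c_one.labels) == {1}
        with pytest.raises(ValueError):
            lq.upgma_cluster(D, K=7)

    def test_newick_depths_are_half_heights(self):
        """Leaf-to-root depth in the exported tree equals half the final
        merge height (ultrametric with halved branch lengths)."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(12)
        d = random_distance_matrix(7, rng)
        D = DistanceMatrix(ids=tuple("abcdefg"), values=d)
        dendro, _, nwk = lq.upgma_cluster(D, K=2)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, dendro.heights[-1] / 2, atol=1e-6)


class TestClusterMeans:
    def test_single_cluster_equals_overall(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        clus = lq.ClusterAssignment(
            labels=pd.Series([1] * 5, index=list("abcde")), K=1
        )
        out = lq.cluster_means(m, clus)
        assert np.allclose(out.loc[1], out.loc["overall"])

    def test_singleton_cluster_is_that_accession(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"))
        clus = lq.ClusterAssignment(
            labels=pd.Series([1, 2, 2, 2], index=list("abcd")), K=2
        )
        out = lq.cluster_means(m, clus)
        assert np.allclose(out.loc[1], m.loc["a"])

    def test_equal_clusters_conserve_overall_mean(self):
        rng = np.random.default_rng(15)
        m = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"))
        clus = lq.ClusterAssignment(
            labels=pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef")), K=2
        )
        out = lq.cluster_means(m, clus)
        assert np.allclose((out.loc[1] + out.loc[2]) / 2, out.loc["overall"])

    def test_unknown_accession_raises(self):
        m = pd.DataFrame(np.eye(2), index=["a", "b"])
        clus = lq.ClusterAssignment(
            labels=pd.Series([1, 2], index=["a", "zzz"]), K=2
        )
        with pytest.raises(KeyError, match="zzz"):
            lq.cluster_means(m, clus)
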