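"""F_ST, D_A, Rosenberg informativeness, PCA, MDS, NJ and clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popkit import divergence
from popkit.divergence import (
    DistanceMatrix,
    classical_mds,
    cumulative_in,
    da_matrix,
    fst_matrix,
    hclust_order,
    informativeness_in,
    nei_da,
    nj_tree,
    pairwise_fst,
    pca,
)
from popkit.forensic import LocusFrequencies


def freqs_from_matrix(rows: dict[str, list[float]], n: int = 100) -> LocusFrequencies:
    recs = [
        (pop, f"L{j + 1}", p, n)
        for pop, ps in rows.items()
        for j, p in enumerate(ps)
    ]
    return LocusFrequencies(
        pd.DataFrame(recs, columns=LocusFrequencies.COLUMNS))


class TestFst:
    def test_identical_frequencies_zero(self):
        f = freqs_from_matrix({"A": [0.2, 0.7], "B": [0.2, 0.7]})
        assert pairwise_fst(f, "A", "B") == 0.0

    def test_single_locus_hand_value(self):
        f = freqs_from_matrix({"A": [0.9], "B": [0.1]})
        assert pairwise_fst(f, "A", "B") == pytest.approx(0.64)

    def test_symmetric_in_population_order(self):
        f = freqs_from_matrix({"A": [0.9, 0.3], "B": [0.1, 0.6]})
        assert pairwise_fst(f, "A", "B") == pairwise_fst(f, "B", "A")

    def test_matrix_properties(self, panel_freqs):
        m = fst_matrix(panel_freqs.population)
        v = m.values
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        assert ((v >= 0) & (v <= 1)).all()

    def test_no_shared_loci_rejected(self):
        f = LocusFrequencies(pd.DataFrame(
            [("A", "L1", 0.5, 10), ("B", "L2", 0.5, 10)],
            columns=LocusFrequencies.COLUMNS))
        with pytest.raises(ValueError):
            pairwise_fst(f, "A", "B")


class TestNeiDa:
    def test_identical_frequencies_zero(self):
        f = freqs_from_matrix({"A": [0.4], "B": [0.4]})
        assert nei_da(f, "A", "B") == pytest.approx(0.0)

    def test_single_locus_hand_value(self):
        f = freqs_from_matrix({"A": [0.9], "B": [0.1]})
        assert nei_da(f, "A", "B") == pytest.approx(0.4)

    def test_fixed_difference_is_maximal(self):
        f = freqs_from_matrix({"A": [1.0, 1.0], "B": [0.0, 0.0]})
        assert nei_da(f, "A", "B") == pytest.approx(1.0)

    def test_matrix_bounds(self, panel_freqs):
        v = da_matrix(panel_freqs.population).values
        assert ((v >= 0) & (v <= 1)).all() and np.allclose(v, v.T)


class TestInformativeness:
    def test_identical_groups_zero(self):
        assert informativeness_in([0.3, 0.3, 0.3]) == pytest.approx(0.0, abs=1e-12)

    def test_two_group_hand_value(self):
        assert informativeness_in([0.9, 0.1]) == pytest.approx(0.368070, abs=1e-5)

    def test_fixed_difference_attains_ln2(self):
        i_n = informativeness_in([1.0, 0.0])
        assert i_n == pytest.approx(math.log(2))
        assert i_n / math.log(2) == pytest.approx(1.0)  # PSD = 1

    def test_bounded_by_log_k(self):
        rng = np.random.default_rng(0)
        for k in (2, 3, 5):
            for _ in range(50):
                p = rng.random(k)
                assert 0.0 <= informativeness_in(p) <= math.log(k) + 1e-12

    def test_matches_brute_force_summation(self):
        """Oracle equivalence with a literal term-by-term evaluation."""

        def brute(ps):
            K = len(ps)
            total = 0.0
            for freqs in (ps, [1 - x for x in ps]):
                pbar = sum(freqs) / K
                term = -pbar * math.log(pbar) if pbar > 0 else 0.0
                for x in freqs:
                    if x > 0:
                        term += x * math.log(x) / K
                total += term
            return total

        rng = np.random.default_rng(42)
        for k in (2, 3, 5, 8):
            for _ in range(40):
                p = rng.random(k).tolist()
                assert informativeness_in(p) == pytest.approx(
                    brute(p), abs=1e-12)


class TestCumulativeIn:
    def test_single_locus_equals_per_locus(self):
        f = freqs_from_matrix({"A": [0.9], "B": [0.1], "C": [0.5]})
        cum, per = cumulative_in(f, ("A", "B"))
        assert cum == pytest.approx(per.iloc[0])
        assert cum == pytest.approx(informativeness_in([0.9, 0.1]))

    def test_additive_over_duplicated_locus(self):
        f1 = freqs_from_matrix({"A": [0.9], "B": [0.1]})
        f2 = freqs_from_matrix({"A": [0.9, 0.9], "B": [0.1, 0.1]})
        c1, _ = cumulative_in(f1, ("A", "B"))
        c2, _ = cumulative_in(f2, ("A", "B"))
        assert c2 == pytest.approx(2 * c1)

    def test_divergent_group_attains_maximum_one_vs_rest(self):
        rows = {g: [0.45, 0.5, 0.55, 0.5] for g in ("B", "C", "D", "E")}
        rows["A"] = [0.95, 0.05, 0.9, 0.1]  # strongly differentiated group
        f = freqs_from_matrix(rows)
        cums = {g: cumulative_in(f, g)[0] for g in rows}
        assert max(cums, key=cums.get) == "A"

    def test_empty_group_rejected(self):
        f = freqs_from_matrix({"A": [0.5]})
        with pytest.raises(ValueError):
            cumulative_in(f, "A")


class TestPca:
    def test_axis_aligned_clouds(self):
        # variance 9 along x, 1 along y, zero covariance: components = axes
        x = np.array([-3.0, 3, -3, 3])
        y = np.array([1.0, 1, -1, -1])
        res = pca(pd.DataFrame({"x": x, "y": y}), standardize=False)
        assert res.explained_fraction[0] == pytest.approx(
            x.var() / (x.var() + y.var()))
        assert abs(res.coordinates["PC1"].to_numpy()).max() == pytest.approx(3.0)

    def test_cos2_sums_to_one_standardized_full_rank(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((8, 4)), columns=list("abcd"))
        res = pca(m, standardize=True)
        assert np.allclose(res.cos2.sum(axis=1), 1.0, atol=1e-8)

    def test_duplicate_entities_identical_scores(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((5, 3)))
        m2 = pd.concat([m, m.iloc[[0]]], ignore_index=True)
        res = pca(m2, standardize=False)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[-1])

    def test_zero_variance_feature_dropped_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1],
                          "c": [4.0, 3, 2, 1]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(m, standardize=True)
        assert "b" not in res.cos2.index

    def test_contributions_sum_to_100(self, panel_freqs):
        res = pca(panel_freqs.population.matrix(), standardize=True)
        assert np.allclose(res.contributions.sum(axis=0), 100.0)


class TestClassicalMds:
    def test_collinear_points_recovered(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = classical_mds(DistanceMatrix(["a", "b", "c"], D), k=1)
        c = res.coordinates.to_numpy().ravel()
        rec = np.abs(c[:, None] - c[None, :])
        assert np.allclose(rec, D, atol=1e-9)

    def test_two_points_separated_by_d(self):
        D = np.array([[0.0, 2.5], [2.5, 0.0]])
        res = classical_mds(DistanceMatrix(["a", "b"], D), k=1)
        c = res.coordinates.to_numpy().ravel()
        assert abs(c[0] - c[1]) == pytest.approx(2.5)

    def test_all_zero_matrix(self):
        D = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            res = classical_mds(DistanceMatrix(list("abc"), D), k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_planar_points_distances_exact(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([str(i) for i in range(6)], D), k=2)
        c = res.coordinates.to_numpy()
        rec = np.sqrt(((c[:, None] - c[None, :]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-9)


class TestNjTree:
    @staticmethod
    def _leaf_distances(newick: str):
        import io

        from skbio import TreeNode

        t = TreeNode.read(io.StringIO(newick))
        return t.tip_tip_distances()

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) with internal edge 1 between AB and CD
        D = np.array([
            [0.0, 3, 5, 6],
            [3, 0.0, 6, 7],
            [5, 6, 0.0, 7],
            [6, 7, 7, 0.0],
        ])
        nwk = nj_tree(DistanceMatrix(list("ABCD"), D, "DA"))
        dm = self._leaf_distances(nwk)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert dm[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 4, 6], [4, 0.0, 8], [6, 8, 0.0]])
        nwk = nj_tree(DistanceMatrix(list("XYZ"), D))
        dm = self._leaf_distances(nwk)
        assert dm["X", "Y"] == pytest.approx(4)
        assert dm["X", "Z"] == pytest.approx(6)
        assert dm["Y", "Z"] == pytest.approx(8)

    def test_label_order_invariance(self):
        import dendropy

        rng = np.random.default_rng(4)
        pts = rng.random((6, 3))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(6)]
        nwk1 = nj_tree(DistanceMatrix(labels, D))
        perm = rng.permutation(6)
        nwk2 = nj_tree(DistanceMatrix([labels[i] for i in perm],
                                      D[np.ix_(perm, perm)]))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions(); t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0.0]])))


class TestHclustOrder:
    def test_planted_partition_recovered(self):
        import scipy.cluster.hierarchy as sch

        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, (5, 4))
        b = rng.normal(5, 0.1, (5, 4))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)])
        out = hclust_order(m)
        cut = sch.fcluster(out["row_linkage"], 2, criterion="maxclust")
        assert len(set(cut[:5])) == 1 and len(set(cut[5:])) == 1
        assert cut[0] != cut[5]
        # leaf order keeps the two planted clusters contiguous
        order = out["row_order"]
        first_block = {lab[0] for lab in order[:5]}
        assert first_block in ({"A"}, {"B"})

    def test_identical_rows_merge_at_height_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        out = hclust_order(m)
        assert out["row_linkage"][0, 2] == pytest.approx(0.0)

    def test_single_entity_trivial(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        out = hclust_order(m)
        assert out["row_order"] == ["only"] and out["row_linkage"] is None


class TestDistanceMatrixContainer:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))
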