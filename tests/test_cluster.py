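"""Centered-Pearson distance, complete linkage (vs naive oracle), TreeView I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbmcsig import (
    DistanceMatrix,
    ExpressionMatrix,
    centered_pearson_distance,
    complete_linkage,
    simulate_expression,
    write_treeview,
)
from pbmcsig.cluster import read_gtr
from pbmcsig.exceptions import (
    DomainError,
    InsufficientOverlapError,
    UndefinedCorrelationError,
)

from conftest import clean_config


def _em(cols: dict) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame(
        cols, index=pd.Index([f"s{i}" for i in range(len(next(iter(cols.values()))))],
                             name="spot_id")))


def naive_complete_linkage(ids, d):
    """Brute-force reference: recompute max over all cross pairs each merge."""
    clusters = {i: [i] for i in range(len(ids))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return heights


class TestDistance:
    def test_identical_vectors_zero(self):
        m = _em({"u": [1.0, 2.0, 3.0], "v": [1.0, 2.0, 3.0]})
        d = centered_pearson_distance(m, axis="samples")
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_two(self):
        m = _em({"u": [1.0, 2.0, 3.0], "v": [3.0, 2.0, 1.0]})
        d = centered_pearson_distance(m, axis="samples")
        assert d.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_after_centering_is_one(self):
        m = _em({"u": [1.0, -1.0, 0.0], "v": [1.0, 1.0, -2.0]})
        d = centered_pearson_distance(m, axis="samples")
        assert d.d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_shift_and_positive_scale_invariance(self):
        rng = np.random.default_rng(5)
        u = rng.normal(0, 1, 30)
        v = rng.normal(0, 1, 30)
        d0 = centered_pearson_distance(_em({"u": u, "v": v})).d[0, 1]
        d1 = centered_pearson_distance(_em({"u": 3.7 * u + 2.0, "v": v})).d[0, 1]
        assert d1 == pytest.approx(d0, abs=1e-10)

    def test_pairwise_complete_positions(self):
        u = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        v = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        d = centered_pearson_distance(_em({"u": u, "v": v})).d[0, 1]
        # shared positions 0,1,2 are perfectly correlated
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_overlap_names_pair(self):
        u = np.array([1.0, 2.0, np.nan, np.nan])
        v = np.array([np.nan, 4.0, 1.0, 2.0])
        with pytest.raises(InsufficientOverlapError, match="'u'.*'v'"):
            centered_pearson_distance(_em({"u": u, "v": v}))

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            centered_pearson_distance(_em({"u": [1.0, 1.0, 1.0], "v": [1.0, 2.0, 3.0]}))

    def test_gene_axis(self):
        m = _em({"a": [1.0, 1.0], "b": [2.0, 3.0], "c": [3.0, 5.0]})
        d = centered_pearson_distance(m, axis="genes")
        assert d.ids == ["s0", "s1"]
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestCompleteLinkage:
    def test_two_items(self):
        d = DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = complete_linkage(d)
        assert tree.merges == [("NODE1X", "a", "b", 0.4)]

    def test_three_item_hand_example(self):
        d = DistanceMatrix(ids=["a", "b", "c"], d=np.array([
            [0.0, 0.1, 0.9],
            [0.1, 0.0, 0.5],
            [0.9, 0.5, 0.0]]))
        tree = complete_linkage(d)
        assert tree.merges[0][:3] == ("NODE1X", "a", "b")
        assert tree.merges[0][3] == pytest.approx(0.1)
        assert tree.merges[1][3] == pytest.approx(0.9)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            x = rng.random((n, n))
            d = np.triu(x, 1)
            d = d + d.T
            dist = DistanceMatrix(ids=[f"i{k}" for k in range(n)], d=d, metric="test")
            tree = complete_linkage(dist)
            np.testing.assert_allclose(
                tree.heights, naive_complete_linkage(dist.ids, d), atol=1e-12)

    def test_matches_scipy_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(23)
        x = rng.random((10, 10))
        d = np.triu(x, 1)
        d = d + d.T
        dist = DistanceMatrix(ids=[f"i{k}" for k in range(10)], d=d, metric="test")
        tree = complete_linkage(dist)
        Z = linkage(squareform(d), method="complete")
        np.testing.assert_allclose(sorted(tree.heights), sorted(Z[:, 2]), atol=1e-10)

    def test_heights_monotone(self):
        rng = np.random.default_rng(29)
        x = rng.random((12, 12))
        d = np.triu(x, 1)
        d = d + d.T
        tree = complete_linkage(DistanceMatrix(
            ids=[f"i{k}" for k in range(12)], d=d, metric="test"))
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_single_item_rejected(self):
        with pytest.raises(DomainError):
            complete_linkage(DistanceMatrix(ids=["a"], d=np.zeros((1, 1))))

    def test_two_group_signal_recovers_labels(self):
        # strong case/control signal: the top split separates the groups
        cfg = clean_config(
            n_case_subjects=20, n_control_subjects=20,
            n_genes=100, n_de_genes=100, de_log2fc_range=(2.0, 2.0),
            residual_sd=0.3, seed=31)
        m, s, t = simulate_expression(cfg)
        dist = centered_pearson_distance(m.subset_spots(t.de_spots), axis="samples")
        tree = complete_linkage(dist)
        left, right = tree.top_split()
        groups = s.groups
        agree = max(
            (groups.loc[left] == "case").sum() + (groups.loc[right] == "control").sum(),
            (groups.loc[left] == "control").sum() + (groups.loc[right] == "case").sum(),
        ) / len(groups)
        assert agree >= 0.95


class TestTreeView:
    def _matrix_and_tree(self):
        m = _em({"a": [0.1, 0.2, 0.3], "b": [0.2, 0.1, 0.4], "c": [0.9, 0.8, 0.1]})
        d = DistanceMatrix(ids=["a", "b", "c"], d=np.array([
            [0.0, 0.1, 0.9],
            [0.1, 0.0, 0.5],
            [0.9, 0.5, 0.0]]))
        return m, complete_linkage(d)

    def test_cdt_only_without_trees(self, tmp_path):
        m, _ = self._matrix_and_tree()
        files = write_treeview(m, None, None, tmp_path / "out")
        assert [f.rsplit(".", 1)[1] for f in files] == ["cdt"]
        lines = (tmp_path / "out.cdt").read_text().splitlines()
        assert lines[0].startswith("UNIQID\tNAME\tGWEIGHT")
        assert [ln.split("\t")[0] for ln in lines[2:]] == ["s0", "s1", "s2"]

    def test_atr_similarities(self, tmp_path):
        m, tree = self._matrix_and_tree()
        write_treeview(m, None, tree, tmp_path / "out")
        atr = (tmp_path / "out.atr").read_text().splitlines()
        sims = [float(ln.split("\t")[3]) for ln in atr]
        assert sims == pytest.approx([0.9, 0.1])  # 1 - heights 0.1, 0.9

    def test_gtr_round_trip(self, tmp_path):
        m, tree = self._matrix_and_tree()
        write_treeview(m, None, tree, tmp_path / "out")
        back = read_gtr(tmp_path / "out.atr", leaves=["a", "b", "c"])
        assert [mg[:3] for mg in back.merges] == [mg[:3] for mg in tree.merges]
        np.testing.assert_allclose(back.heights, tree.heights, atol=1e-9)

    def test_leaf_order_follows_tree(self, tmp_path):
        m, tree = self._matrix_and_tree()
        write_treeview(m, None, tree, tmp_path / "out")
        header = (tmp_path / "out.cdt").read_text().splitlines()[0].split("\t")
        assert header[3:] == tree.leaf_order()
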