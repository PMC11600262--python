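"""Pearson correlation, median-split rank-sum, and edge annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from litreg.confidence import (
    ExpressionError,
    ExpressionMatrix,
    attach_confidence,
    band,
    median_split_ranksum,
    pearson,
)
from litreg.corpus import EntitySpan, RelationTriple
from litreg.graph import SynonymTable, aggregate
from litreg.simulate import GeneratorConfig, generate_expression


def matrix(genes_values: dict) -> ExpressionMatrix:
    df = pd.DataFrame(genes_values).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestPearson:
    def test_identical_vectors(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_half_correlation(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ExpressionError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ExpressionError):
            pearson([1, 2], [3, 4])

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            a, b = rng.uniform(0.1, 5.0), rng.normal()
            assert pearson(x, y) == pytest.approx(pearson(y, x))
            assert pearson(a * x + b, y) == pytest.approx(pearson(x, y))

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)


class TestRanksum:
    def test_clean_separation_exact_p(self):
        # split gene divides samples into (1,2) vs (3,4) on the test
        # gene; U = 0 and all-assignments enumeration gives p = 1/3
        m = matrix({"SPLIT": [0, 0, 1, 1], "TEST": [1, 2, 3, 4]})
        u, p = median_split_ranksum(m, "SPLIT", "TEST")
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_constant_test_gene(self):
        m = matrix({"SPLIT": [0, 0, 1, 1], "TEST": [5, 5, 5, 5]})
        _, p = median_split_ranksum(m, "SPLIT", "TEST")
        assert p == 1.0

    def test_label_swap_symmetry(self):
        m1 = matrix({"SPLIT": [0, 0, 1, 1, 0, 1], "TEST": [3, 1, 4, 1, 5, 9]})
        m2 = matrix({"SPLIT": [1, 1, 0, 0, 1, 0], "TEST": [3, 1, 4, 1, 5, 9]})
        _, p1 = median_split_ranksum(m1, "SPLIT", "TEST")
        _, p2 = median_split_ranksum(m2, "SPLIT", "TEST")
        assert p1 == pytest.approx(p2)

    def test_ties_go_to_low_group(self):
        # median of (1, 2, 2, 3) is 2; ties at the median join the low
        # group, so the split is 3 vs 1 -> degenerate high group
        m = matrix({"SPLIT": [1, 2, 2, 3], "TEST": [1, 2, 3, 4]})
        with pytest.raises(ExpressionError):
            median_split_ranksum(m, "SPLIT", "TEST")

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            vals = rng.permutation(10).astype(float)
            split = np.r_[np.zeros(5), np.ones(5)]
            m = matrix({"SPLIT": split, "TEST": vals})
            u, p = median_split_ranksum(m, "SPLIT", "TEST")
            ref = stats.mannwhitneyu(vals[:5], vals[5:], method="exact",
                                     alternative="two-sided")
            assert p == pytest.approx(ref.pvalue)

    def test_exact_matches_full_enumeration_small_n(self):
        # independent oracle: recompute via scipy permutation_test over
        # the U statistic with exact enumeration
        rng = np.random.default_rng(3)
        vals = rng.normal(size=8)
        split = np.r_[np.zeros(4), np.ones(4)]
        m = matrix({"SPLIT": split, "TEST": vals})
        u, p = median_split_ranksum(m, "SPLIT", "TEST")

        def u_stat(a, b):
            d = np.asarray(a)[:, None] - np.asarray(b)[None, :]
            return np.sum(d > 0) + 0.5 * np.sum(d == 0)

        m_tot = 16
        ref = stats.permutation_test(
            (vals[:4], vals[4:]),
            lambda a, b: u_stat(a, b) - m_tot / 2,
            permutation_type="independent", n_resamples=np.inf,
            alternative="two-sided",
        )
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        split = rng.normal(size=40)
        test = split * 0.8 + rng.normal(size=40) * 0.3
        m = matrix({"SPLIT": split, "TEST": test})
        u, p = median_split_ranksum(m, "SPLIT", "TEST")
        ref = stats.mannwhitneyu(
            test[split <= np.median(split)], test[split > np.median(split)],
            method="asymptotic", alternative="two-sided", use_continuity=True,
        )
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_gene_errors(self):
        m = matrix({"SPLIT": [0, 0, 1, 1], "TEST": [1, 2, 3, 4]})
        with pytest.raises(KeyError):
            median_split_ranksum(m, "SPLIT", "NOPE")


class TestExpressionMatrix:
    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame([[1, 2, 3], [4, 5, 6]], index=["G", "G"])
        with pytest.raises(ExpressionError):
            ExpressionMatrix(df)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["G"])
        with pytest.raises(ExpressionError):
            ExpressionMatrix(df)

    def test_non_finite_rejected(self):
        df = pd.DataFrame([[1.0, np.nan, 3.0]], index=["G"])
        with pytest.raises(ExpressionError):
            ExpressionMatrix(df)

    def test_tsv_round_trip(self, tmp_path):
        m = matrix({"WNT4": [1.0, 2.0, 3.0], "STAT3": [0.5, 0.1, 0.9]})
        path = tmp_path / "expr.tsv"
        m.write_tsv(path)
        back = ExpressionMatrix.read_tsv(path)
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)


def edge_graph():
    t = SynonymTable.from_rows([])
    a = EntitySpan(0, 1, "Gene", surface="WNT4")
    b = EntitySpan(2, 3, "Gene", surface="STAT3")
    c = EntitySpan(2, 3, "Gene", surface="NODATA")
    f = EntitySpan(2, 3, "BiologicalFunction", surface="apoptosis")
    triples = [
        RelationTriple(a, "Promotes", b, doc_id="D1"),
        RelationTriple(a, "Inhibits", c, doc_id="D2"),
        RelationTriple(a, "Function", f, doc_id="D3"),
    ]
    g = aggregate(triples, t)
    # normalize() lower-cases unknown genes; relabel to matrix symbols
    mapping = {"wnt4": "WNT4", "stat3": "STAT3", "nodata": "NODATA"}
    import networkx as nx
    g.g = nx.relabel_nodes(g.g, mapping)
    return g


class TestAttachConfidence:
    def test_bands(self):
        assert band(0.1) == "weak"
        assert band(-0.45) == "moderate"
        assert band(0.95) == "strong"

    def test_annotation_and_no_data_markers(self):
        g = edge_graph()
        m = matrix({"WNT4": [1, 2, 3, 4, 5], "STAT3": [1.1, 2.2, 2.9, 4.2, 4.8]})
        out = attach_confidence(g, m)
        by_key = {(u, k, v): d for u, k, v, d in out.edges()}
        strong = by_key[("WNT4", "Promotes", "STAT3")]
        assert strong["confidence"] == "strong" and strong["r"] > 0.9
        assert by_key[("WNT4", "Inhibits", "NODATA")]["confidence"] == "no-data"
        assert by_key[("WNT4", "Function", "apoptosis")]["confidence"] == "no-data"
        assert out.g.graph["confidence_annotated"]

    def test_input_graph_unmodified(self):
        g = edge_graph()
        m = matrix({"WNT4": [1, 2, 3, 4], "STAT3": [2, 1, 4, 3]})
        before = g.to_node_link()
        attach_confidence(g, m)
        assert g.to_node_link() == before

    def test_planted_correlation_recovered(self):
        cfg = GeneratorConfig(n_samples=50)
        rs = []
        for rep in range(100):
            em = generate_expression(cfg, seed=1000 + rep)
            rs.append(pearson(em.values_for("WNT4"), em.values_for("STAT3")))
        assert abs(np.mean(rs) - 0.9) < 0.05
        assert all(abs(r - 0.9) < 0.2 for r in rs)
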