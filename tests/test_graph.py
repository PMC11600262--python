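"""Normalization, aggregation, filtering, and path queries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from litreg.corpus import EntitySpan, RelationTriple
from litreg.graph import (
    RegulatoryGraph,
    SynonymTable,
    aggregate,
    filter_graph,
    find_intermediaries,
    normalize,
)


@pytest.fixture()
def table():
    return SynonymTable.from_rows([
        ("WNT4", ["WNT-4", "Wnt4"]),
        ("STAT3", ["STAT-3"]),
        ("IGF2", ["IGF-II", "Igf2"]),
    ])


def triple(s, p, o, doc="D1", sent=0, s_label="Gene", o_label="Gene"):
    a = EntitySpan(0, 1, s_label, surface=s, sentence_index=sent)
    b = EntitySpan(2, 3, o_label, surface=o, sentence_index=sent)
    return RelationTriple(a, p, b, doc_id=doc, sentence_index=sent)


class TestNormalize:
    def test_alias_lookup(self, table):
        assert normalize("Wnt-4", "Gene", table) == "WNT4"

    def test_standard_symbol_identity(self, table):
        assert normalize("WNT4", "Gene", table) == "WNT4"

    def test_non_gene_pass_through(self, table):
        assert normalize("Cell  Migration", "BiologicalFunction", table) == (
            "cell migration"
        )

    def test_unknown_gene_casefolds(self, table):
        assert normalize("Novel1", "Gene", table) == "novel1"

    def test_ambiguous_alias_kept_as_surface(self):
        t = SynonymTable.from_rows([("A1", ["shared"]), ("B2", ["shared"])])
        assert "shared" in t.ambiguous
        assert normalize("SHARED", "Gene", t) == "shared"

    def test_tsv_dialect(self, tmp_path, table):
        path = tmp_path / "syn.tsv"
        path.write_text(
            "Symbol\tSynonyms\nWNT4\tWNT-4|Wnt4\nSTAT3\t-\n"
        )
        t = SynonymTable.from_tsv(path)
        assert t.lookup("wnt-4") == "WNT4"
        assert t.lookup("STAT3") == "STAT3"
        assert t.lookup("-") is None


class TestAggregate:
    def test_same_relation_two_docs_merges(self, table):
        g = aggregate(
            [triple("WNT4", "Promotes", "IGF2", doc="D1"),
             triple("WNT4", "Promotes", "IGF2", doc="D2")],
            table,
        )
        assert g.n_edges() == 1
        [(u, k, v, d)] = list(g.edges())
        assert (u, k, v) == ("WNT4", "Promotes", "IGF2")
        assert d["weight"] == 2 and len(d["provenance"]) == 2

    def test_aliases_merge_to_one_edge(self, table):
        g = aggregate(
            [triple("Wnt-4", "Promotes", "IGF-II", doc="D1"),
             triple("WNT4", "Promotes", "IGF2", doc="D2")],
            table,
        )
        assert g.n_edges() == 1 and g.n_nodes() == 2

    def test_empty(self, table):
        g = aggregate([], table)
        assert g.n_nodes() == 0 and g.n_edges() == 0

    def test_same_doc_same_sentence_counts_once(self, table):
        g = aggregate(
            [triple("WNT4", "Promotes", "IGF2", doc="D1", sent=2)] * 2, table
        )
        assert g.total_weight() == 1

    def test_self_loop_dropped(self, table):
        g = aggregate([triple("WNT4", "Promotes", "Wnt-4")], table)
        assert g.n_edges() == 0

    def test_weight_conservation(self, table):
        rng = np.random.default_rng(0)
        names = ["WNT4", "STAT3", "IGF2", "GENX"]
        triples = [
            triple(names[i], "Promotes", names[j], doc=f"D{k}", sent=int(s))
            for k, (i, j, s) in enumerate(
                zip(rng.integers(0, 4, 30), rng.integers(0, 4, 30),
                    rng.integers(0, 3, 30))
            )
            if i != j
        ]
        g = aggregate(triples, table)
        assert g.total_weight() == len(triples)

    def test_order_invariance(self, table):
        triples = [
            triple("WNT4", "Promotes", "STAT3", doc="D1"),
            triple("STAT3", "Inhibits", "IGF2", doc="D2"),
            triple("Wnt4", "Promotes", "STAT-3", doc="D3"),
        ]
        a = aggregate(triples, table).to_node_link()
        b = aggregate(triples[::-1], table).to_node_link()
        assert a == b

    def test_abbreviation_extends_synonyms_not_edges(self, table):
        # NOVEL9, via an abbreviation to a known alias, resolves to IGF2
        abbrev = triple("IGF-II", "Abbreviation", "NOVEL9", doc="D0")
        reg = triple("WNT4", "Promotes", "NOVEL9", doc="D1")
        g = aggregate([abbrev, reg], table)
        assert g.n_edges() == 1
        [(u, k, v, _)] = list(g.edges())
        assert v == "IGF2"

    def test_year_recorded_in_provenance(self, table):
        g = aggregate([triple("WNT4", "Promotes", "IGF2", doc="D1")], table,
                      doc_years={"D1": 2018})
        [(_, _, _, d)] = list(g.edges())
        assert d["provenance"][0][1] == 2018


@pytest.fixture()
def filter_fixture(table):
    triples = (
        [triple("WNT4", "Promotes", "STAT3", doc=f"P{i}") for i in range(3)]
        + [triple("STAT3", "Promotes", "IGF2", doc=f"Q{i}") for i in range(2)]
        + [triple("WNT4", "Inhibits", "GENX", doc="R0")]
    )
    years = {"P0": 2012, "P1": 2016, "P2": 2021, "Q0": 2016, "Q1": 2017,
             "R0": 2019}
    return aggregate(triples, table, doc_years=years)


class TestFilter:
    def test_min_weight(self, filter_fixture):
        g = filter_graph(filter_fixture, min_weight=2)
        weights = sorted(d["weight"] for *_, d in g.edges())
        assert weights == [2, 3]

    def test_predicate_filter(self, filter_fixture):
        g = filter_graph(filter_fixture, predicates={"Promotes"})
        assert all(k == "Promotes" for _, k, _, _ in g.edges())
        assert g.n_edges() == 2

    def test_year_range(self, filter_fixture):
        g = filter_graph(filter_fixture, year_range=(2015, 2020))
        kept = {(u, k, v) for u, k, v, _ in g.edges()}
        assert kept == {("WNT4", "Promotes", "STAT3"),
                        ("STAT3", "Promotes", "IGF2"),
                        ("WNT4", "Inhibits", "genx")}
        g2 = filter_graph(filter_fixture, year_range=(2022, 2030))
        assert g2.n_edges() == 0

    def test_no_filters_is_identity(self, filter_fixture):
        assert filter_graph(filter_fixture).to_node_link() == (
            filter_fixture.to_node_link()
        )

    def test_filters_commute(self, filter_fixture):
        a = filter_graph(
            filter_graph(filter_fixture, predicates={"Promotes"}), min_weight=2
        )
        b = filter_graph(
            filter_graph(filter_fixture, min_weight=2), predicates={"Promotes"}
        )
        assert a.to_node_link() == b.to_node_link()

    def test_orphans_pruned(self, filter_fixture):
        g = filter_graph(filter_fixture, predicates={"Inhibits"})
        assert set(g.g.nodes) == {"WNT4", "genx"}

    def test_input_unmodified(self, filter_fixture):
        before = filter_fixture.to_node_link()
        filter_graph(filter_fixture, min_weight=99)
        assert filter_fixture.to_node_link() == before

    def test_unknown_predicate_errors(self, filter_fixture):
        with pytest.raises(ValueError):
            filter_graph(filter_fixture, predicates={"Binds"})

    def test_missing_year_passes_by_default(self, table):
        g = aggregate([triple("WNT4", "Promotes", "IGF2")], table)
        assert filter_graph(g, year_range=(1990, 1991)).n_edges() == 1


def brute_force_paths(graph, source, target, max_len):
    """All simple directed regulatory paths by explicit enumeration."""
    simple = {}
    for u, k, v, d in graph.edges():
        if k in ("Promotes", "Inhibits", "Upstream"):
            if (u, v) not in simple or d["weight"] > simple[(u, v)]:
                simple[(u, v)] = d["weight"]
    nodes = {n for uv in simple for n in uv}
    found = []
    for length in range(1, max_len + 1):
        for mids in itertools.permutations(nodes - {source, target}, length - 1):
            path = [source, *mids, target]
            if all((a, b) in simple for a, b in zip(path, path[1:])):
                found.append(
                    (length, -min(simple[(a, b)] for a, b in zip(path, path[1:])),
                     path)
                )
    return sorted(found)


class TestIntermediaries:
    def test_two_hop(self, table):
        g = aggregate(
            [triple("A1", "Promotes", "B2", doc="D1"),
             triple("B2", "Promotes", "C3", doc="D2")],
            table,
        )
        [r] = find_intermediaries(g, "a1", "c3", max_len=3)
        assert r["intermediaries"] == ["b2"]

    def test_direct_edge_ranks_first(self, table):
        g = aggregate(
            [triple("A1", "Promotes", "C3", doc="D1"),
             triple("A1", "Promotes", "B2", doc="D2"),
             triple("B2", "Promotes", "C3", doc="D3")],
            table,
        )
        results = find_intermediaries(g, "a1", "c3", max_len=3)
        assert results[0]["intermediaries"] == []
        assert results[0]["length"] == 1

    def test_stronger_short_path_ranks_first(self, table):
        triples = (
            [triple("WNT4", "Promotes", "STAT3", doc=f"P{i}") for i in range(3)]
            + [triple("STAT3", "Promotes", "IGF2", doc=f"Q{i}") for i in range(3)]
            + [triple("WNT4", "Promotes", "GENX", doc="R0"),
               triple("GENX", "Promotes", "GENY", doc="R1"),
               triple("GENY", "Promotes", "IGF2", doc="R2")]
        )
        results = find_intermediaries(
            aggregate(triples, SynonymTable.from_rows([])), "wnt4", "igf2", 3
        )
        assert results[0]["intermediaries"] == ["stat3"]
        assert results[0]["min_weight"] == 3

    def test_missing_endpoint_errors(self, table):
        g = aggregate([triple("A1", "Promotes", "B2")], table)
        with pytest.raises(KeyError):
            find_intermediaries(g, "nope", "b2")

    def test_no_path_empty(self, table):
        g = aggregate(
            [triple("A1", "Promotes", "B2"), triple("C3", "Promotes", "B2")],
            table,
        )
        assert find_intermediaries(g, "a1", "c3") == []

    def test_function_edges_excluded_from_paths(self, table):
        g = aggregate(
            [triple("A1", "Function", "B2", o_label="BiologicalFunction"),
             triple("B2", "Promotes", "C3")],
            table,
        )
        # the only A1->B2 link is a Function edge, so no regulatory path
        assert find_intermediaries(g, "a1", "c3") == []

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        empty = SynonymTable.from_rows([])
        for trial in range(10):
            n = int(rng.integers(4, 9))
            names = [f"N{i}" for i in range(n)]
            triples = []
            for k in range(int(rng.integers(5, 18))):
                i, j = rng.choice(n, size=2, replace=False)
                triples.append(
                    triple(names[i], "Promotes", names[j], doc=f"D{k % 5}",
                           sent=k)
                )
            g = aggregate(triples, empty)
            src, dst = "n0", f"n{n - 1}"
            if src not in g.g or dst not in g.g:
                continue
            got = find_intermediaries(g, src, dst, max_len=4)
            expected = brute_force_paths(g, src, dst, max_len=4)
            assert [(r["length"], -r["min_weight"], r["path"]) for r in got] == (
                expected
            )


class TestExport:
    def test_node_link_round_trip(self, filter_fixture, tmp_path):
        path = tmp_path / "g.json"
        filter_fixture.write_json(path)
        back = RegulatoryGraph.read_json(path)
        assert back.to_node_link() == filter_fixture.to_node_link()

    def test_graphml_readable(self, filter_fixture, tmp_path):
        path = tmp_path / "g.graphml"
        filter_fixture.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == filter_fixture.n_edges()

    def test_edge_tsv(self, filter_fixture, tmp_path):
        path = tmp_path / "edges.tsv"
        filter_fixture.write_edge_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + filter_fixture.n_edges()
        assert lines[0].split("\t") == ["subject", "predicate", "object",
                                        "weight", "doc_ids"]
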