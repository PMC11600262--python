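"""Normalization, aggregation, and querying of the regulatory graph.

Typed relation triples are standardized (gene aliases mapped to one
symbol through an NCBI gene_info-style synonym table), deduplicated
per (document, sentence), and merged into a directed multigraph whose
edge weight is the number of distinct supporting mentions and whose
provenance records each (doc_id, year, sentence_index). Abbreviation
triples are not edges: they extend the synonym table within the run,
which is what keeps node identity unique. The graph can be filtered
by predicate, edge frequency, and publication-year range, and queried
for intermediary molecules on directed regulatory paths.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from litreg.corpus import PREDICATES, RelationTriple

log = logging.getLogger(__name__)

REGULATORY_PREDICATES = ("Promotes", "Inhibits", "Upstream")


# ---------------------------------------------------------------------------
# Synonym table and normalization
# ---------------------------------------------------------------------------

@dataclass
class SynonymTable:
    """Case-folded alias -> standard-symbol map.

    An alias claimed by more than one symbol is ambiguous; lookups on
    it fail (the mention keeps its own surface as a node) rather than
    guessing an identity.
    """

    alias_to_symbol: dict[str, str] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    @classmethod
    def from_rows(cls, rows) -> "SynonymTable":
        """Build from (symbol, aliases) rows; symbols map to themselves."""
        t = cls()
        for symbol, aliases in rows:
            t.add(symbol, aliases)
        return t

    @classmethod
    def from_tsv(cls, path) -> "SynonymTable":
        """Read the gene_info dialect: Symbol <tab> pipe-separated Synonyms."""
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "Symbol":
                    continue
                symbol = row[0].strip()
                aliases = [a.strip() for a in (row[1] if len(row) > 1 else "").split("|")
                           if a.strip() and a.strip() != "-"]
                rows.append((symbol, aliases))
        return cls.from_rows(rows)

    def add(self, symbol: str, aliases) -> None:
        for name in [symbol, *aliases]:
            k = name.casefold()
            prev = self.alias_to_symbol.get(k)
            if prev is not None and prev != symbol:
                self.ambiguous.add(k)
                log.warning("ambiguous alias %r: %s vs %s", name, prev, symbol)
            else:
                self.alias_to_symbol[k] = symbol

    def lookup(self, surface: str) -> str | None:
        k = surface.casefold()
        if k in self.ambiguous:
            return None
        return self.alias_to_symbol.get(k)

    def copy(self) -> "SynonymTable":
        return SynonymTable(dict(self.alias_to_symbol), set(self.ambiguous))


def normalize(surface: str, label: str, table: SynonymTable) -> str:
    """Node identifier for one mention.

    Genes resolve case-insensitively through the synonym table; an
    unknown or ambiguous gene surface, and every non-gene mention,
    becomes its case-folded whitespace-collapsed surface.
    """
    collapsed = " ".join(surface.split())
    if label == "Gene":
        symbol = table.lookup(collapsed)
        if symbol is not None:
            return symbol
        if collapsed.casefold() in table.ambiguous:
            log.warning("ambiguous gene alias %r kept as its own node", surface)
    return collapsed.casefold()


# ---------------------------------------------------------------------------
# Graph container
# ---------------------------------------------------------------------------

class RegulatoryGraph:
    """Directed multigraph keyed by (subject, predicate, object).

    Thin wrapper over :class:`networkx.MultiDiGraph`: nodes carry an
    entity label, edges carry ``weight`` (supporting-mention count)
    and ``provenance`` (list of (doc_id, year, sentence_index)).
    """

    def __init__(self) -> None:
        self.g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------
    def add_support(self, subj: str, subj_label: str, pred: str,
                    obj: str, obj_label: str,
                    doc_id: str, year: int | None, sentence_index: int) -> None:
        self.g.add_node(subj, label=subj_label)
        self.g.add_node(obj, label=obj_label)
        if not self.g.has_edge(subj, obj, key=pred):
            self.g.add_edge(subj, obj, key=pred, weight=0, provenance=[])
        data = self.g[subj][obj][pred]
        data["provenance"].append((doc_id, year, sentence_index))
        data["weight"] = len(data["provenance"])

    # -- views ---------------------------------------------------------
    def edges(self):
        """Iterate (subject, predicate, object, data)."""
        for u, v, k, d in self.g.edges(keys=True, data=True):
            yield u, k, v, d

    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def total_weight(self) -> int:
        return sum(d["weight"] for *_, d in self.edges())

    def copy(self) -> "RegulatoryGraph":
        out = RegulatoryGraph()
        out.g = self.g.copy()
        # deep-copy mutable edge attributes
        for u, v, k, d in out.g.edges(keys=True, data=True):
            d["provenance"] = list(d["provenance"])
        return out

    # -- export --------------------------------------------------------
    def to_node_link(self) -> dict:
        return {
            "directed": True,
            "nodes": [{"id": n, "label": d.get("label", "")}
                      for n, d in sorted(self.g.nodes(data=True))],
            "links": [
                {
                    "source": u, "target": v, "predicate": k,
                    "weight": d["weight"],
                    "provenance": [
                        {"doc_id": p[0], "year": p[1], "sentence_index": p[2]}
                        for p in d["provenance"]
                    ],
                }
                for u, v, k, d in sorted(self.g.edges(keys=True, data=True))
            ],
        }

    @classmethod
    def from_node_link(cls, payload: dict) -> "RegulatoryGraph":
        out = cls()
        for n in payload["nodes"]:
            out.g.add_node(n["id"], label=n.get("label", ""))
        for e in payload["links"]:
            prov = [(p["doc_id"], p.get("year"), p["sentence_index"])
                    for p in e["provenance"]]
            out.g.add_edge(e["source"], e["target"], key=e["predicate"],
                           weight=len(prov), provenance=prov)
        return out

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_node_link(), fh, indent=1)

    @classmethod
    def read_json(cls, path) -> "RegulatoryGraph":
        with open(path, encoding="utf-8") as fh:
            return cls.from_node_link(json.load(fh))

    def write_graphml(self, path) -> None:
        g = nx.MultiDiGraph()
        for n, d in self.g.nodes(data=True):
            g.add_node(n, label=d.get("label", ""))
        for u, v, k, d in self.g.edges(keys=True, data=True):
            g.add_edge(u, v, key=k, predicate=k, weight=d["weight"],
                       provenance=json.dumps(d["provenance"]))
        nx.write_graphml(g, path)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["subject", "predicate", "object", "weight", "doc_ids"])
            for u, k, v, d in sorted(self.edges()):
                w.writerow([u, k, v, d["weight"],
                            ";".join(p[0] for p in d["provenance"])])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(
    triples: list[RelationTriple],
    table: SynonymTable,
    doc_years: dict[str, int | None] | None = None,
) -> RegulatoryGraph:
    """Deduplicate, standardize, and merge triples into a graph.

    Abbreviation triples extend a run-scoped copy of the synonym table
    (alias -> standard symbol) instead of becoming edges. Duplicate
    support within one (doc_id, sentence_index) counts once;
    normalization-induced self-loops are dropped and logged. The
    result is independent of input order.
    """
    doc_years = doc_years or {}
    table = table.copy()

    # First pass: harvest abbreviation pairs to extend alias coverage.
    for t in sorted((t for t in triples if t.predicate == "Abbreviation"),
                    key=lambda t: t.key()):
        if t.subject.label != "Gene" or t.object.label != "Gene":
            continue
        s_sym = table.lookup(" ".join(t.subject.surface.split()))
        o_sym = table.lookup(" ".join(t.object.surface.split()))
        if s_sym is not None and o_sym is None:
            table.add(s_sym, [" ".join(t.object.surface.split())])
        elif o_sym is not None and s_sym is None:
            table.add(o_sym, [" ".join(t.subject.surface.split())])

    graph = RegulatoryGraph()
    seen: set[tuple] = set()
    for t in sorted((t for t in triples if t.predicate != "Abbreviation"),
                    key=lambda t: t.key() + (t.doc_id,)):
        s = normalize(t.subject.surface, t.subject.label, table)
        o = normalize(t.object.surface, t.object.label, table)
        if s == o:
            log.info("dropping self-loop %s -%s-> %s (%s)",
                     s, t.predicate, o, t.doc_id)
            continue
        support = (s, t.predicate, o, t.doc_id, t.sentence_index)
        if support in seen:
            continue
        seen.add(support)
        graph.add_support(
            s, t.subject.label, t.predicate, o, t.object.label,
            t.doc_id, doc_years.get(t.doc_id), t.sentence_index,
        )
    return graph


# ---------------------------------------------------------------------------
# Filtering and path queries
# ---------------------------------------------------------------------------

def filter_graph(
    graph: RegulatoryGraph,
    predicates: set[str] | None = None,
    min_weight: int | None = None,
    year_range: tuple[int, int] | None = None,
) -> RegulatoryGraph:
    """New graph keeping edges that pass every active filter.

    Year filter: an edge passes when at least one provenance year
    falls inside the inclusive range; supports with no year pass by
    default (logged). Orphaned nodes are pruned; the input graph is
    untouched.
    """
    if predicates is not None:
        unknown = set(predicates) - set(PREDICATES)
        if unknown:
            raise ValueError(f"unknown predicates {sorted(unknown)}")
    out = RegulatoryGraph()
    for u, k, v, d in graph.edges():
        if predicates is not None and k not in predicates:
            continue
        if min_weight is not None and d["weight"] < min_weight:
            continue
        if year_range is not None:
            lo, hi = year_range
            years = [p[1] for p in d["provenance"]]
            if any(y is None for y in years):
                log.info("edge %s-%s->%s has support without a year; kept",
                         u, k, v)
            if not any(y is None or lo <= y <= hi for y in years):
                continue
        out.g.add_node(u, **graph.g.nodes[u])
        out.g.add_node(v, **graph.g.nodes[v])
        out.g.add_edge(u, v, key=k, weight=d["weight"],
                       provenance=list(d["provenance"]))
    return out


def find_intermediaries(
    graph: RegulatoryGraph,
    source: str,
    target: str,
    max_len: int = 3,
):
    """Directed regulatory paths source -> target, ranked.

    Only Promotes/Inhibits/Upstream edges participate. Paths of up to
    ``max_len`` edges are ranked by (length ascending, then minimum
    edge weight along the path descending). Each result reports the
    interior (intermediary) nodes, the node path, the predicate chosen
    on each hop (the strongest when parallel edges exist), and the
    bottleneck weight. Missing endpoints raise ``KeyError``; no path
    yields an empty list.
    """
    if source not in graph.g:
        raise KeyError(f"source node {source!r} not in graph")
    if target not in graph.g:
        raise KeyError(f"target node {target!r} not in graph")
    # collapse parallel regulatory edges to the strongest per pair
    simple = nx.DiGraph()
    for u, k, v, d in graph.edges():
        if k not in REGULATORY_PREDICATES:
            continue
        prev = simple.get_edge_data(u, v)
        if prev is None or d["weight"] > prev["weight"]:
            simple.add_edge(u, v, weight=d["weight"], predicate=k)
    if source not in simple or target not in simple:
        return []
    results = []
    for path in nx.all_simple_paths(simple, source, target, cutoff=max_len):
        hops = [simple[a][b] for a, b in zip(path, path[1:])]
        results.append(
            {
                "intermediaries": path[1:-1],
                "path": path,
                "predicates": [h["predicate"] for h in hops],
                "min_weight": min(h["weight"] for h in hops),
                "length": len(path) - 1,
            }
        )
    results.sort(key=lambda r: (r["length"], -r["min_weight"], r["path"]))
    return results
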