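"""Seeded generator of annotated abstracts and expression matrices.

Stands in for a curated corpus of PubMed abstracts: templated
sentences with exact gold entity spans and relation triples covering
all four entity types and all five predicates, plus distractor
sentences that mention entities without relating them (so relation
training sees true negatives). A companion generator draws
multivariate-normal expression matrices with a planted correlation
structure, so expression-confidence annotation can be validated
against known ground truth.

The gene vocabulary is synthetic (GENA1, GENA2, ...) plus WNT4, STAT3
and IGF2, so the WNT4 -> STAT3 -> IGF2 intermediary query works out of
the box. Everything is a deterministic function of the config seed.

The generator targets mechanism coverage, not linguistic realism:
templates are short, unambiguous, and free of negation, coordination
and anaphora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from litreg.corpus import (
    PREDICATES,
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    tokenize,
)
from litreg.confidence import ExpressionMatrix


class SimulationError(ValueError):
    pass


_REAL_GENES = ("WNT4", "STAT3", "IGF2")
_REAL_ALIASES = {
    "WNT4": ["WNT-4", "Wnt4"],
    "STAT3": ["STAT-3", "Stat3"],
    "IGF2": ["IGF-II", "Igf2"],
}
_PATHWAY_BASE = ["JAK-STAT", "PI3K-AKT", "MAPK", "NOTCH", "HEDGEHOG", "TGF-beta"]
_CANCER_BASE = [
    "colon cancer", "breast cancer", "gastric cancer", "lung cancer",
    "hepatocellular carcinoma", "ovarian cancer", "pancreatic cancer",
    "prostate cancer",
]
_FUNCTION_BASE = [
    "cell migration", "cell proliferation", "cell adhesion", "apoptosis",
    "angiogenesis", "tumor growth", "immune evasion", "drug resistance",
]

_PROMOTE_VERBS = ["promotes", "activates", "upregulates", "enhances"]
_INHIBIT_VERBS = ["inhibits", "suppresses", "represses", "downregulates"]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 1
    n_train: int = 300
    n_test: int = 100
    n_validation: int = 50
    n_genes: int = 30
    n_pathways: int = 6
    n_cancers: int = 6
    n_functions: int = 8
    #: proportions over (Promotes, Inhibits, Upstream, Abbreviation, Function)
    relation_mix: tuple[float, ...] = (0.30, 0.25, 0.15, 0.15, 0.15)
    alias_prob: float = 0.3
    distractor_prob: float = 0.25
    year_range: tuple[int, int] = (2010, 2024)
    n_samples: int = 14
    #: planted pairwise correlations (gene_a, gene_b, rho)
    correlations: tuple[tuple[str, str, float], ...] = (
        ("WNT4", "STAT3", 0.9),
        ("STAT3", "IGF2", 0.9),
        ("WNT4", "IGF2", 0.81),
    )

    def validate(self) -> None:
        if len(self.relation_mix) != len(PREDICATES):
            raise SimulationError("relation_mix needs one proportion per predicate")
        if any(p < 0 for p in self.relation_mix) or not np.isclose(
            sum(self.relation_mix), 1.0
        ):
            raise SimulationError("relation_mix must be non-negative and sum to 1")
        if self.n_genes < len(_REAL_GENES):
            raise SimulationError(f"n_genes must be >= {len(_REAL_GENES)}")
        for n in (self.n_pathways, self.n_cancers, self.n_functions):
            if n < 1:
                raise SimulationError("vocabulary sizes must be positive")
        if not 0.0 <= self.alias_prob <= 1.0:
            raise SimulationError("alias_prob must lie in [0, 1]")


@dataclass
class Vocabulary:
    genes: list[str]
    aliases: dict[str, list[str]]
    pathways: list[str]
    cancers: list[str]
    functions: list[str]


def build_vocabulary(config: GeneratorConfig) -> Vocabulary:
    genes = list(_REAL_GENES) + [
        f"GENA{i}" for i in range(1, config.n_genes - len(_REAL_GENES) + 1)
    ]
    aliases = dict(_REAL_ALIASES)
    for g in genes[len(_REAL_GENES):]:
        i = g[4:]
        aliases[g] = [f"GENA-{i}", f"Gena{i}"]
    pathways = (_PATHWAY_BASE + [f"SIGP{i}" for i in range(1, 1000)])[: config.n_pathways]
    cancers = (_CANCER_BASE + [f"subtype-{i} carcinoma" for i in range(1, 1000)])[
        : config.n_cancers
    ]
    functions = (_FUNCTION_BASE + [f"pathway-{i} signaling output" for i in range(1, 1000)])[
        : config.n_functions
    ]
    return Vocabulary(genes, aliases, pathways, cancers, functions)


# ---------------------------------------------------------------------------
# Sentence assembly
# ---------------------------------------------------------------------------

class _SentenceBuilder:
    def __init__(self, sentence_index: int):
        self.tokens: list[str] = []
        self.entities: list[EntitySpan] = []
        self.sentence_index = sentence_index

    def words(self, text: str) -> None:
        self.tokens.extend(text.split())

    def entity(self, surface: str, label: str) -> EntitySpan:
        parts = surface.split()
        start = len(self.tokens)
        self.tokens.extend(parts)
        span = EntitySpan(
            start, start + len(parts), label,
            surface=surface, sentence_index=self.sentence_index,
        )
        self.entities.append(span)
        return span


def _gene_surface(rng, vocab: Vocabulary, gene: str, alias_prob: float) -> tuple[str, str | None]:
    """(surface, alias_used): mention the gene by symbol or alias."""
    if vocab.aliases.get(gene) and rng.random() < alias_prob:
        alias = vocab.aliases[gene][rng.integers(len(vocab.aliases[gene]))]
        return alias, alias
    return gene, None


def _build_sentence(rng, vocab, config, sentence_index, alias_log):
    """One templated sentence; returns (builder, triples-as-entity-pairs)."""
    b = _SentenceBuilder(sentence_index)
    triples: list[tuple[EntitySpan, str, EntitySpan]] = []

    def gene_entity(gene: str) -> EntitySpan:
        surface, alias = _gene_surface(rng, vocab, gene, config.alias_prob)
        if alias is not None:
            alias_log.setdefault(gene, set()).add(alias)
        return b.entity(surface, "Gene")

    def two_genes() -> tuple[str, str]:
        i, j = rng.choice(len(vocab.genes), size=2, replace=False)
        return vocab.genes[i], vocab.genes[j]

    if rng.random() < config.distractor_prob:
        form = rng.integers(4)
        if form == 0:
            b.words("The role of")
            gene_entity(vocab.genes[rng.integers(len(vocab.genes))])
            b.words("in")
            b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
            b.words("remains unclear .")
        elif form == 1:
            c = vocab.cancers[rng.integers(len(vocab.cancers))]
            b.entity(c[0].upper() + c[1:], "Cancer")
            b.words("is a common malignancy worldwide .")
        elif form == 2:
            b.words("Expression of")
            gene_entity(vocab.genes[rng.integers(len(vocab.genes))])
            b.words("was measured in")
            b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
            b.words("samples .")
        else:
            b.words("Previous studies described")
            b.entity(vocab.functions[rng.integers(len(vocab.functions))],
                     "BiologicalFunction")
            b.words("in")
            b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
            b.words(".")
        return b, triples

    pred = PREDICATES[rng.choice(len(PREDICATES), p=list(config.relation_mix))]
    if pred in ("Promotes", "Inhibits"):
        verbs = _PROMOTE_VERBS if pred == "Promotes" else _INHIBIT_VERBS
        verb = verbs[rng.integers(len(verbs))]
        g1, g2 = two_genes()
        pathway_subject = rng.random() < 0.15
        if pathway_subject:
            subj = b.entity(vocab.pathways[rng.integers(len(vocab.pathways))],
                            "SignalPathway")
            b.words("signaling " + verb)
        else:
            subj = gene_entity(g1)
            b.words(verb)
        if rng.random() < 0.35:
            b.words("the")
            obj = b.entity(vocab.pathways[rng.integers(len(vocab.pathways))],
                           "SignalPathway")
            b.words("pathway .")
        else:
            obj = gene_entity(g2)
            b.words("in")
            b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
            b.words(".")
        triples.append((subj, pred, obj))
    elif pred == "Upstream":
        g1, g2 = two_genes()
        subj = gene_entity(g1)
        b.words("acts upstream of")
        if rng.random() < 0.3:
            b.words("the")
            obj = b.entity(vocab.pathways[rng.integers(len(vocab.pathways))],
                           "SignalPathway")
            b.words("pathway .")
        else:
            obj = gene_entity(g2)
            b.words(".")
        triples.append((subj, "Upstream", obj))
    elif pred == "Abbreviation":
        gene = vocab.genes[rng.integers(len(vocab.genes))]
        alias_pool = vocab.aliases.get(gene) or [gene]
        alias = alias_pool[rng.integers(len(alias_pool))]
        alias_log.setdefault(gene, set()).add(alias)
        subj = b.entity(gene, "Gene")
        b.words(", also known as")
        obj = b.entity(alias, "Gene")
        b.words(", is highly expressed in")
        b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
        b.words(".")
        triples.append((subj, "Abbreviation", obj))
    else:  # Function
        g1, _ = two_genes()
        subj = gene_entity(g1)
        if rng.random() < 0.5:
            b.words("is involved in")
            obj = b.entity(vocab.functions[rng.integers(len(vocab.functions))],
                           "BiologicalFunction")
            b.words(".")
        else:
            b.words("contributes to")
            obj = b.entity(vocab.functions[rng.integers(len(vocab.functions))],
                           "BiologicalFunction")
            b.words("in")
            b.entity(vocab.cancers[rng.integers(len(vocab.cancers))], "Cancer")
            b.words(".")
        triples.append((subj, "Function", obj))
    return b, triples


def _build_document(rng, vocab, config, doc_id: str, alias_log) -> AnnotatedDocument:
    n_sent = int(rng.integers(2, 6))
    builders = []
    for s in range(n_sent):
        builders.append(_build_sentence(rng, vocab, config, s, alias_log))
    text = " ".join(" ".join(b.tokens) for b, _ in builders)
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
    doc = tokenize(text, doc_id=doc_id, year=year)
    # the templates must tokenize back to exactly the intended tokens
    if doc.n_sentences() != n_sent or any(
        doc.sentence_tokens(s) != builders[s][0].tokens for s in range(n_sent)
    ):
        raise SimulationError(f"template/tokenizer mismatch in {doc_id}")
    entities: list[EntitySpan] = []
    relations: list[RelationTriple] = []
    for b, triples in builders:
        entities.extend(b.entities)
        for subj, pred, obj in triples:
            relations.append(
                RelationTriple(subj, pred, obj, doc_id=doc_id,
                               sentence_index=subj.sentence_index)
            )
    return AnnotatedDocument(doc, entities, relations)


@dataclass
class CorpusBundle:
    splits: dict[str, list[AnnotatedDocument]]
    synonym_rows: list[tuple[str, list[str]]]
    config: GeneratorConfig
    vocabulary: Vocabulary

    @property
    def all_documents(self) -> list[AnnotatedDocument]:
        return [d for split in self.splits.values() for d in split]

    def doc_years(self) -> dict[str, int | None]:
        return {d.document.doc_id: d.document.year for d in self.all_documents}


def generate_corpus(config: GeneratorConfig | None = None) -> CorpusBundle:
    """Annotated train/test/validation splits plus the synonym table rows.

    Split by document. The emitted synonym rows cover every alias the
    corpus actually used (abbreviation definitions included), so every
    alias resolves to a corpus symbol; with ``alias_prob = 0`` and no
    abbreviation sentences the table maps only symbols to themselves.
    """
    config = config or GeneratorConfig()
    config.validate()
    vocab = build_vocabulary(config)
    rng = np.random.default_rng(config.seed)
    alias_log: dict[str, set[str]] = {}
    splits: dict[str, list[AnnotatedDocument]] = {}
    counter = 0
    for name, n in (("train", config.n_train), ("test", config.n_test),
                    ("validation", config.n_validation)):
        docs = []
        for _ in range(n):
            counter += 1
            docs.append(
                _build_document(rng, vocab, config, f"SYN{counter:05d}", alias_log)
            )
        splits[name] = docs
    synonym_rows = [
        (g, sorted(alias_log.get(g, set()))) for g in vocab.genes
    ]
    return CorpusBundle(splits, synonym_rows, config, vocab)


def write_synonym_tsv(rows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Symbol\tSynonyms\n")
        for symbol, aliases in rows:
            fh.write(f"{symbol}\t{'|'.join(aliases) if aliases else '-'}\n")


# ---------------------------------------------------------------------------
# Expression matrices with planted correlation
# ---------------------------------------------------------------------------

def planted_correlation_matrix(genes: list[str], correlations) -> np.ndarray:
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    C = np.eye(n)
    for a, b, rho in correlations:
        if a not in idx or b not in idx:
            raise SimulationError(f"correlation names unknown gene: {a!r}/{b!r}")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-10:
        raise SimulationError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g})"
        )
    return C


def generate_expression(
    config: GeneratorConfig | None = None,
    genes: list[str] | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Multivariate-normal draws with the planted correlation structure.

    Gene symbols match the corpus vocabulary; sample ids are S01, S02,
    ... Values are unit-variance z-scores (already "normalized"
    expression).
    """
    config = config or GeneratorConfig()
    config.validate()
    if genes is None:
        genes = build_vocabulary(config).genes
    C = planted_correlation_matrix(genes, config.correlations)
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    # eigen decomposition handles the PSD-but-singular case cleanly
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    A = V @ np.diag(np.sqrt(w))
    Z = rng.standard_normal((len(genes), config.n_samples))
    X = A @ Z
    df = pd.DataFrame(
        X, index=genes,
        columns=[f"S{j + 1:02d}" for j in range(config.n_samples)],
    )
    return ExpressionMatrix(df)
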