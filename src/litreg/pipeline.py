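"""End-to-end wiring: NER -> RE -> integration, and corpus-level scoring."""

from __future__ import annotations

from litreg.corpus import AnnotatedDocument
from litreg.evaluate import (
    match_spans,
    match_triples,
    merge_counts,
    report,
)
from litreg.integrate import CompatibilityTable, integrate
from litreg.ner import NerModel
from litreg.relations import ReModel


def extract_document(
    ner_model: NerModel,
    re_model: ReModel,
    doc,
    table: CompatibilityTable | None = None,
) -> AnnotatedDocument:
    """Predicted entities and integrated typed triples for one document."""
    table = table or CompatibilityTable()
    entities = ner_model.predict_document(doc)
    head_triples = re_model.predict_document(doc)
    relations = integrate(entities, head_triples, table, doc_id=doc.doc_id)
    return AnnotatedDocument(doc, entities, relations)


def extract_corpus(ner_model, re_model, docs, table=None) -> list[AnnotatedDocument]:
    table = table or CompatibilityTable()
    return [extract_document(ner_model, re_model, d, table) for d in docs]


def evaluate_extraction(
    gold_docs: list[AnnotatedDocument],
    pred_docs: list[AnnotatedDocument],
) -> dict:
    """Entity and relation reports pooled over paired documents.

    Documents are paired positionally and must refer to the same
    texts; counts are micro-averaged across the corpus.
    """
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and predicted corpora differ in size")
    span_parts, triple_parts = [], []
    for g, p in zip(gold_docs, pred_docs):
        if g.document.doc_id != p.document.doc_id:
            raise ValueError(
                f"document mismatch: {g.document.doc_id} vs {p.document.doc_id}"
            )
        span_parts.append(match_spans(g.entities, p.entities))
        triple_parts.append(match_triples(g.relations, p.relations))
    return {
        "entities": report(merge_counts(span_parts)),
        "relations": report(merge_counts(triple_parts)),
    }
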