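"""Fusion of NER spans with head-level RE triples.

Relation types between entities are contextually constrained — e.g.
an abbreviation relation cannot hold between a gene and a biological
function — so integration anchors each predicted head-token pair in
recognized entity spans, restores the full typed spans, and keeps the
triple only when the (subject label, predicate, object label)
combination is allowed. Integration is a pure filter: it never
invents a triple, which is why it trades recall for precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from litreg.corpus import (
    ENTITY_LABELS,
    PREDICATES,
    EntitySpan,
    RelationTriple,
)

_REGULATORY = ("Promotes", "Inhibits", "Upstream")


def _default_rules() -> dict[tuple[str, str, str], bool]:
    """Biologically conservative defaults honouring the hard constraint.

    * Promotes/Inhibits/Upstream: subject must be a gene or pathway;
      any of the four types may be regulated.
    * Function: only gene/pathway -> biological function.
    * Abbreviation: only between mentions of the same type (in
      particular gene–function abbreviation is always disallowed).
    """
    rules: dict[tuple[str, str, str], bool] = {}
    for s in ENTITY_LABELS:
        for p in PREDICATES:
            for o in ENTITY_LABELS:
                if p in _REGULATORY:
                    ok = s in ("Gene", "SignalPathway")
                elif p == "Function":
                    ok = s in ("Gene", "SignalPathway") and o == "BiologicalFunction"
                else:  # Abbreviation
                    ok = s == o
                rules[(s, p, o)] = ok
    return rules


@dataclass
class CompatibilityTable:
    """Total map (subject label, predicate, object label) -> allowed."""

    rules: dict[tuple[str, str, str], bool] = field(default_factory=_default_rules)

    def allowed(self, subject_label: str, predicate: str, object_label: str) -> bool:
        return self.rules[(subject_label, predicate, object_label)]

    @classmethod
    def all_permissive(cls) -> "CompatibilityTable":
        return cls({(s, p, o): True for s in ENTITY_LABELS
                    for p in PREDICATES for o in ENTITY_LABELS})

    @classmethod
    def from_tsv(cls, path) -> "CompatibilityTable":
        """Read (subject_label, predicate, object_label, allowed) rows.

        Unlisted combinations fall back to the defaults, so a file may
        override selectively.
        """
        rules = _default_rules()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "subject_label":
                    continue
                s, p, o, flag = row[:4]
                if s not in ENTITY_LABELS or o not in ENTITY_LABELS:
                    raise ValueError(f"unknown entity label in rule {row!r}")
                if p not in PREDICATES:
                    raise ValueError(f"unknown predicate in rule {row!r}")
                rules[(s, p, o)] = flag.strip().lower() in ("1", "true", "yes")
        return cls(rules)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["subject_label", "predicate", "object_label", "allowed"])
            for (s, p, o), ok in sorted(self.rules.items()):
                w.writerow([s, p, o, int(ok)])


def integrate(
    entities: list[EntitySpan],
    head_triples,
    table: CompatibilityTable | None = None,
    doc_id: str = "",
) -> list[RelationTriple]:
    """Promote head-level triples to full typed relation triples.

    ``head_triples`` are (sentence_index, subject_head, predicate,
    object_head) tuples from the RE stage. A triple survives only if
    both heads fall inside recognized entity spans of the same
    sentence and the resulting label combination is allowed. The
    output is a subset of the anchored candidates — integration only
    filters. Idempotent: integrating full triples reduced back to
    heads reproduces them.
    """
    table = table or CompatibilityTable()
    by_sent: dict[int, list[EntitySpan]] = {}
    for e in entities:
        by_sent.setdefault(e.sentence_index, []).append(e)

    def covering(sent: int, head: int) -> EntitySpan | None:
        for e in by_sent.get(sent, []):
            if e.start <= head < e.end:
                return e
        return None

    out: list[RelationTriple] = []
    for sent, s_head, pred, o_head in head_triples:
        subj = covering(sent, s_head)
        obj = covering(sent, o_head)
        if subj is None or obj is None:
            continue
        if (subj.start, subj.end) == (obj.start, obj.end):
            continue
        if not table.allowed(subj.label, pred, obj.label):
            continue
        out.append(
            RelationTriple(subj, pred, obj, doc_id=doc_id, sentence_index=sent)
        )
    return out
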