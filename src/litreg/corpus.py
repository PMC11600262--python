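"""Document model, rule-based tokenization, and the BIO tag codec.

Conventions used throughout the package:

* character offsets are 0-based, half-open ``[start, end)``;
* entity spans are **token-index** intervals local to one sentence,
  also half-open;
* entity labels come from a closed four-label set and relation
  predicates from a closed five-label set;
* the annotated-corpus interchange format is JSONL, one document per
  line, with *global* (document-flattened) token indices so the schema
  needs no nested sentence bookkeeping.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ENTITY_LABELS = ("Gene", "SignalPathway", "Cancer", "BiologicalFunction")
PREDICATES = ("Promotes", "Inhibits", "Upstream", "Abbreviation", "Function")

#: BIO alphabet in fixed order; index 0 is O, then B/I pairs per label.
BIO_TAGS = ("O",) + tuple(
    f"{p}-{lab}" for lab in ENTITY_LABELS for p in ("B", "I")
)
TAG_INDEX = {t: i for i, t in enumerate(BIO_TAGS)}

# Abbreviations whose trailing period must not end a sentence.
_ABBREVS = frozenset(
    {"e.g.", "i.e.", "et al.", "al.", "fig.", "figs.", "vs.", "ca.", "cf.",
     "dr.", "no.", "approx."}
)

_PUNCT = set(".,;:!?()[]{}\"'`")


class CorpusError(ValueError):
    """Invalid document, annotation, or tag input."""


@dataclass(frozen=True)
class EntitySpan:
    """Typed entity mention: token-index span within one sentence."""

    start: int
    end: int
    label: str
    surface: str = ""
    sentence_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in ENTITY_LABELS:
            raise CorpusError(f"unknown entity label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    def key(self) -> tuple[int, int, int, str]:
        return (self.sentence_index, self.start, self.end, self.label)


@dataclass(frozen=True)
class RelationTriple:
    """Directed relation between two entity spans in one sentence."""

    subject: EntitySpan
    predicate: str
    object: EntitySpan
    doc_id: str = ""
    sentence_index: int = 0

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise CorpusError(f"unknown predicate {self.predicate!r}")
        if self.subject.sentence_index != self.object.sentence_index:
            raise CorpusError("relation arguments must share a sentence")
        if (self.subject.start, self.subject.end) == (
            self.object.start,
            self.object.end,
        ):
            raise CorpusError("subject and object must be distinct spans")

    def key(self) -> tuple:
        return (
            self.sentence_index,
            self.subject.key(),
            self.predicate,
            self.object.key(),
        )


@dataclass
class Document:
    """Tokenized text: sentence and token character intervals.

    ``tokens[i]`` lists the half-open character intervals of sentence
    ``i``'s tokens; all intervals index into ``text``.
    """

    doc_id: str
    text: str
    year: int | None = None
    journal: str | None = None
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[list[tuple[int, int]]] = field(default_factory=list)

    def sentence_tokens(self, i: int) -> list[str]:
        return [self.text[a:b] for a, b in self.tokens[i]]

    def n_sentences(self) -> int:
        return len(self.sentences)

    def token_surface(self, sent: int, start: int, end: int) -> str:
        """Text slice covering tokens [start, end) of a sentence."""
        iv = self.tokens[sent]
        return self.text[iv[start][0] : iv[end - 1][1]]


@dataclass
class AnnotatedDocument:
    document: Document
    entities: list[EntitySpan] = field(default_factory=list)
    relations: list[RelationTriple] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def _split_token(text: str, a: int, b: int) -> list[tuple[int, int]]:
    """Split off leading/trailing punctuation of text[a:b] as own tokens.

    Internal punctuation (hyphens in gene names, periods in versions)
    stays inside the token, so "WNT-4" is a single token.
    """
    out: list[tuple[int, int]] = []
    while a < b and text[a] in _PUNCT:
        out.append((a, a + 1))
        a += 1
    tail: list[tuple[int, int]] = []
    while b > a and text[b - 1] in _PUNCT:
        tail.append((b - 1, b))
        b -= 1
    if a < b:
        out.append((a, b))
    out.extend(reversed(tail))
    return out


def _sentence_boundaries(text: str) -> list[tuple[int, int]]:
    """Split on [.!?] followed by whitespace and an uppercase letter.

    A candidate boundary is suppressed when the word ending at the
    terminator is a known abbreviation.
    """
    bounds: list[int] = []
    for m in re.finditer(r"[.!?]", text):
        i = m.end()
        j = i
        while j < len(text) and text[j].isspace():
            j += 1
        if j == i or j >= len(text) or not text[j].isupper():
            continue
        # word ending at the terminator, lowered, including the mark
        k = m.start()
        while k > 0 and not text[k - 1].isspace():
            k -= 1
        word = text[k:i].lower()
        if word in _ABBREVS or ("al." == word and text[:k].rstrip().lower().endswith("et")):
            continue
        bounds.append(i)
    spans: list[tuple[int, int]] = []
    prev = 0
    for b in bounds + [len(text)]:
        a, e = prev, b
        while a < e and text[a].isspace():
            a += 1
        while e > a and text[e - 1].isspace():
            e -= 1
        if a < e:
            spans.append((a, e))
        prev = b
    return spans


def tokenize(
    text: str,
    doc_id: str = "",
    year: int | None = None,
    journal: str | None = None,
) -> Document:
    """Segment text into sentences and tokens, deterministically.

    Rules: sentences end at ``[.!?]`` followed by whitespace and an
    uppercase letter (with an abbreviation stoplist); tokens are
    whitespace-separated words with leading/trailing punctuation split
    off as separate single-character tokens. Hyphenated names remain
    one token.

    Raises :class:`CorpusError` on empty or whitespace-only input.
    """
    if not text or not text.strip():
        raise CorpusError("cannot tokenize empty text")
    sentences = _sentence_boundaries(text)
    tokens: list[list[tuple[int, int]]] = []
    for sa, sb in sentences:
        toks: list[tuple[int, int]] = []
        for m in re.finditer(r"\S+", text[sa:sb]):
            toks.extend(_split_token(text, sa + m.start(), sa + m.end()))
        tokens.append(toks)
    return Document(
        doc_id=doc_id, text=text, year=year, journal=journal,
        sentences=sentences, tokens=tokens,
    )


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

def bio_encode(entities: Sequence[EntitySpan], n_tokens: int) -> list[str]:
    """Encode non-overlapping entity spans as a BIO tag sequence.

    Raises :class:`CorpusError` on overlapping or out-of-range spans.
    """
    tags = ["O"] * n_tokens
    occupied = [False] * n_tokens
    for e in entities:
        if e.end > n_tokens:
            raise CorpusError(
                f"entity span [{e.start}, {e.end}) exceeds {n_tokens} tokens"
            )
        if any(occupied[e.start : e.end]):
            raise CorpusError("overlapping entity spans in gold annotation")
        for i in range(e.start, e.end):
            occupied[i] = True
            tags[i] = f"{'B' if i == e.start else 'I'}-{e.label}"
    return tags


def bio_decode(tags: Sequence[str], sentence_index: int = 0) -> list[EntitySpan]:
    """Decode a BIO sequence into entity spans.

    Ill-formed input (an ``I-X`` run with no opening ``B-X``) is
    repaired by promoting the first ``I-X`` to ``B-X`` — a lossless
    repair that keeps model output well-defined. Unknown tag strings
    raise :class:`CorpusError`.
    """
    spans: list[EntitySpan] = []
    cur_label: str | None = None
    cur_start = 0
    for i, t in enumerate(tags):
        if t not in TAG_INDEX:
            raise CorpusError(f"unknown BIO tag {t!r}")
        if t == "O":
            prefix, label = "O", None
        else:
            prefix, label = t.split("-", 1)
        if prefix == "I" and label == cur_label:
            continue
        if cur_label is not None:
            spans.append(
                EntitySpan(cur_start, i, cur_label, sentence_index=sentence_index)
            )
            cur_label = None
        if prefix in ("B", "I") and label is not None:  # I- here = repair to B-
            cur_label, cur_start = label, i
    if cur_label is not None:
        spans.append(
            EntitySpan(cur_start, len(tags), cur_label, sentence_index=sentence_index)
        )
    return spans


# ---------------------------------------------------------------------------
# JSONL interchange
# ---------------------------------------------------------------------------

def _flat_offsets(doc: Document) -> list[int]:
    """Cumulative token counts: offset of each sentence in the flat index."""
    off = [0]
    for toks in doc.tokens:
        off.append(off[-1] + len(toks))
    return off


def to_record(ad: AnnotatedDocument) -> dict:
    """Serialize one annotated document to a JSON-compatible dict.

    Entity start/end are global token indices over the flattened
    document; relations reference entity list positions.
    """
    doc = ad.document
    off = _flat_offsets(doc)
    ents = []
    index_of: dict[tuple, int] = {}
    for e in ad.entities:
        index_of[e.key()] = len(ents)
        ents.append(
            {
                "start": off[e.sentence_index] + e.start,
                "end": off[e.sentence_index] + e.end,
                "label": e.label,
            }
        )
    rels = []
    for r in ad.relations:
        rels.append(
            {
                "subject_idx": index_of[r.subject.key()],
                "predicate": r.predicate,
                "object_idx": index_of[r.object.key()],
            }
        )
    rec = {"doc_id": doc.doc_id, "year": doc.year, "text": doc.text,
           "entities": ents, "relations": rels}
    if doc.journal:
        rec["journal"] = doc.journal
    return rec


def from_record(rec: dict, lineno: int | None = None) -> AnnotatedDocument:
    """Parse one JSONL record, re-tokenizing the text.

    Global token indices are mapped back onto sentences; an entity
    crossing a sentence boundary is a schema violation.
    """
    where = f" (line {lineno})" if lineno is not None else ""
    for key in ("doc_id", "text"):
        if key not in rec:
            raise CorpusError(f"missing field {key!r}{where}")
    doc = tokenize(
        rec["text"], doc_id=str(rec["doc_id"]),
        year=rec.get("year"), journal=rec.get("journal"),
    )
    off = _flat_offsets(doc)
    total = off[-1]

    def locate(g_start: int, g_end: int, label: str) -> EntitySpan:
        if not (0 <= g_start < g_end <= total):
            raise CorpusError(
                f"token span [{g_start}, {g_end}) out of range 0..{total}{where}"
            )
        s = next(i for i in range(doc.n_sentences()) if off[i + 1] > g_start)
        if g_end > off[s + 1]:
            raise CorpusError(f"entity crosses sentence boundary{where}")
        a, b = g_start - off[s], g_end - off[s]
        return EntitySpan(
            a, b, label, surface=doc.token_surface(s, a, b), sentence_index=s
        )

    entities: list[EntitySpan] = []
    for j, e in enumerate(rec.get("entities", [])):
        try:
            entities.append(locate(int(e["start"]), int(e["end"]), e["label"]))
        except (KeyError, TypeError) as exc:
            raise CorpusError(f"malformed entity #{j}{where}: {exc}") from exc
    relations: list[RelationTriple] = []
    for j, r in enumerate(rec.get("relations", [])):
        try:
            s, o = entities[int(r["subject_idx"])], entities[int(r["object_idx"])]
            relations.append(
                RelationTriple(
                    s, r["predicate"], o,
                    doc_id=doc.doc_id, sentence_index=s.sentence_index,
                )
            )
        except (KeyError, IndexError, TypeError) as exc:
            raise CorpusError(f"malformed relation #{j}{where}: {exc}") from exc
    return AnnotatedDocument(doc, entities, relations)


def read_jsonl(path) -> list[AnnotatedDocument]:
    """Read an annotated corpus; errors carry 1-based line numbers."""
    out: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"invalid JSON (line {lineno}): {exc}") from exc
            out.append(from_record(rec, lineno=lineno))
    return out


def write_jsonl(docs: Iterable[AnnotatedDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ad in docs:
            fh.write(json.dumps(to_record(ad), ensure_ascii=False) + "\n")
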