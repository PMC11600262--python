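"""Scoring and statistical comparison of extraction output.

Exact-match span and triple scoring with per-class and pooled
(micro-averaged) precision/recall/F1, Wilson score intervals for the
binomial proportions, and the McNemar paired test (exact binomial for
few discordant pairs, continuity-corrected chi-square otherwise).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import binom, chi2, norm

from litreg.corpus import EntitySpan, RelationTriple

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """tp/fp/fn per class plus pooled totals (micro-averaging)."""

    per_class: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def pooled(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_class.values())
        fp = sum(v[1] for v in self.per_class.values())
        fn = sum(v[2] for v in self.per_class.values())
        return tp, fp, fn


def _match(gold_items, pred_items, class_of) -> ConfusionCounts:
    """Exact-key one-to-one matching via multiset intersection."""
    g = Counter(gold_items)
    p = Counter(pred_items)
    classes = {class_of(k) for k in g} | {class_of(k) for k in p}
    counts = ConfusionCounts()
    for c in sorted(classes):
        gc = {k: n for k, n in g.items() if class_of(k) == c}
        pc = {k: n for k, n in p.items() if class_of(k) == c}
        tp = sum(min(n, pc.get(k, 0)) for k, n in gc.items())
        fp = sum(pc.values()) - tp
        fn = sum(gc.values()) - tp
        counts.per_class[c] = (tp, fp, fn)
    return counts


def merge_counts(parts: list[ConfusionCounts]) -> ConfusionCounts:
    """Pool per-class counts across documents (micro-averaging)."""
    out = ConfusionCounts()
    for part in parts:
        for c, (tp, fp, fn) in part.per_class.items():
            a, b, d = out.per_class.get(c, (0, 0, 0))
            out.per_class[c] = (a + tp, b + fp, d + fn)
    return out


def match_spans(gold: list[EntitySpan], pred: list[EntitySpan]) -> ConfusionCounts:
    """Exact boundary + label matching; classes are entity labels."""
    key = lambda e: (e.sentence_index, e.start, e.end, e.label)
    return _match([key(e) for e in gold], [key(e) for e in pred],
                  class_of=lambda k: k[3])


def match_triples(gold: list[RelationTriple], pred: list[RelationTriple]) -> ConfusionCounts:
    """Exact subject span, predicate, and object span; classes are predicates."""
    def key(t: RelationTriple):
        return (t.doc_id, t.sentence_index,
                t.subject.start, t.subject.end, t.subject.label,
                t.predicate,
                t.object.start, t.object.end, t.object.label)
    return _match([key(t) for t in gold], [key(t) for t in pred],
                  class_of=lambda k: k[5])


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(P, R, F1); a zero denominator yields 0 with a logged warning."""
    if tp + fp == 0:
        log.warning("precision undefined (no predictions); reporting 0")
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("recall undefined (no gold items); reporting 0")
        r = 0.0
    else:
        r = tp / (tp + fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    z = float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return (max(0.0, (centre - half) / denom),
            min(1.0, (centre + half) / denom))


@dataclass
class PairedOutcomes:
    """Per-item success vectors of two methods on the same items."""

    a: list[bool]
    b: list[bool]

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("paired outcome vectors differ in length")

    def discordant(self) -> tuple[int, int]:
        """(b, c): items where only A succeeds / only B succeeds."""
        b = sum(1 for x, y in zip(self.a, self.b) if x and not y)
        c = sum(1 for x, y in zip(self.a, self.b) if y and not x)
        return b, c


def mcnemar(b: int, c: int, exact_cutoff: int = 25) -> float:
    """Two-sided McNemar p from discordant counts.

    Exact binomial (doubled smaller tail, capped at 1) when
    ``b + c < exact_cutoff``; continuity-corrected chi-square
    otherwise. ``b + c == 0`` returns 1 with a warning.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        log.warning("no discordant pairs; McNemar p = 1 by convention")
        return 1.0
    if n < exact_cutoff:
        k = min(b, c)
        p = 2.0 * float(binom.cdf(k, n, 0.5))
        if b == c:  # both tails coincide at the centre
            p = 1.0
        return min(1.0, p)
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(chi2.sf(stat, df=1))


def mcnemar_paired(outcomes: PairedOutcomes, exact_cutoff: int = 25) -> float:
    b, c = outcomes.discordant()
    return mcnemar(b, c, exact_cutoff)


def report(counts: ConfusionCounts, confidence: float = 0.95) -> dict:
    """Per-class and overall P/R/F1 with Wilson CIs and raw counts."""
    out: dict = {"classes": {}, "confidence": confidence}

    def row(tp: int, fp: int, fn: int) -> dict:
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        entry = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": p, "recall": r, "f1": f1,
        }
        if tp + fp > 0:
            entry["precision_ci"] = wilson_ci(tp, tp + fp, confidence)
        if tp + fn > 0:
            entry["recall_ci"] = wilson_ci(tp, tp + fn, confidence)
        return entry

    for c, (tp, fp, fn) in sorted(counts.per_class.items()):
        out["classes"][c] = row(tp, fp, fn)
    out["overall"] = row(*counts.pooled())
    return out
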