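"""Joint relation extraction via a unified interaction map.

Each sentence of ``L`` tokens is scored as an ``(L + K) x (L + K)``
matrix, where the last ``K = 5`` rows/columns are relation slots in
the fixed order Promotes, Inhibits, Upstream, Abbreviation, Function.
A gold triple (subject, r, object), anchored at span head tokens,
lights exactly three cells:

* ``(head(subject), head(object))``   — entity–entity,
* ``(head(subject), slot(r))``        — subject–relation,
* ``(slot(r), head(object))``         — relation–object,

and a predicted triple is emitted whenever all three cells clear the
decision threshold. The scorer is a query/key dot-product attention
over contextual token representations (shared embedding + projection
+ BiRNN encoder) and learned slot embeddings, trained with mean
element-wise binary cross-entropy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from litreg.corpus import PREDICATES, AnnotatedDocument, Document
from litreg.embeddings import CharWindowEmbedding, LookupEmbedding
from litreg.nn import Adam, BiRNN, glorot

log = logging.getLogger(__name__)

K = len(PREDICATES)
SLOT = {p: i for i, p in enumerate(PREDICATES)}
_EPS = 1e-7


class RelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interaction-map construction / decoding (model-free)
# ---------------------------------------------------------------------------

def build_gold_interaction_map(n_tokens: int, head_triples) -> np.ndarray:
    """Gold {0,1} map from (subject_head, predicate, object_head) triples."""
    m = np.zeros((n_tokens + K, n_tokens + K))
    for s, pred, o in head_triples:
        if pred not in SLOT:
            raise RelationError(f"unknown predicate {pred!r}")
        if not (0 <= s < n_tokens and 0 <= o < n_tokens):
            raise RelationError(
                f"triple head ({s}, {o}) out of range for {n_tokens} tokens"
            )
        r = n_tokens + SLOT[pred]
        m[s, o] = 1.0
        m[s, r] = 1.0
        m[r, o] = 1.0
    return m


def decode_triples(interaction_map: np.ndarray, threshold: float = 0.5):
    """All (subject_head, predicate, object_head) passing the 3-cell rule.

    Sorted by (subject head, relation slot, object head); the
    subject ≠ object diagonal is excluded.
    """
    if not (0.0 < threshold < 1.0):
        raise RelationError("threshold must lie in (0, 1)")
    m = interaction_map
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < K:
        raise RelationError("interaction map must be square (L+K) x (L+K)")
    L = m.shape[0] - K
    hot = m >= threshold
    out = []
    for s in range(L):
        for r in range(K):
            if not hot[s, L + r]:
                continue
            for o in range(L):
                if s != o and hot[s, o] and hot[L + r, o]:
                    out.append((s, PREDICATES[r], o))
    return out


def bce_loss(predicted: np.ndarray, gold: np.ndarray) -> float:
    """Mean element-wise binary cross-entropy, clamped at 1e-7."""
    if predicted.shape != gold.shape:
        raise RelationError(
            f"shape mismatch {predicted.shape} vs {gold.shape}"
        )
    p = np.clip(predicted, _EPS, 1.0 - _EPS)
    return float(-np.mean(gold * np.log(p) + (1.0 - gold) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ReConfig:
    embed_dim: int = 32
    char_dim: int = 24
    proj_dim: int = 48
    hidden: int = 32
    attn_dim: int = 32
    lr: float = 0.01
    epochs: int = 20
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5
    max_sentence_len: int = 80


class ReModel:
    """Interaction-map scorer; construct via :func:`train_re` or load."""

    def __init__(self, lookup: LookupEmbedding, config: ReConfig):
        self.config = config
        self.lookup = lookup
        self.char = CharWindowEmbedding(config.char_dim)
        self.birnn = BiRNN("rnn", config.proj_dim, config.hidden)
        self.params: dict[str, np.ndarray] = {}
        self.loss_history: list[float] = []

    def init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        d_in = c.embed_dim + c.char_dim
        h = c.attn_dim
        self.params = {
            "E": self.lookup.init_table(rng),
            "Wp": glorot(rng, d_in, c.proj_dim),
            "bp": np.zeros(c.proj_dim),
            "Wt": glorot(rng, 2 * c.hidden, h),
            "bt": np.zeros(h),
            "S": rng.normal(0.0, 0.1, size=(K, h)),
            "Wq": glorot(rng, h, h),
            "Wk": glorot(rng, h, h),
        }
        self.params.update(self.birnn.init_params(rng))
        self.lookup.table = self.params["E"]

    def _forward(self, tokens):
        p = self.params
        ids = self.lookup.ids(tokens)
        X = np.concatenate([p["E"][ids], self.char.embed(tokens)], axis=1)
        P = X @ p["Wp"] + p["bp"]
        H, cache = self.birnn.forward(p, P)
        Ut = H @ p["Wt"] + p["bt"]
        U = np.vstack([Ut, p["S"]])
        Q = U @ p["Wq"]
        Km = U @ p["Wk"]
        scores = (Q @ Km.T) / np.sqrt(self.config.attn_dim)
        prob = expit(scores)
        return ids, X, P, H, cache, U, Q, Km, prob

    def score_map(self, tokens) -> np.ndarray:
        """Predicted interaction map, values in (0, 1)."""
        return self._forward(tokens)[-1]

    def loss_and_grads(self, tokens, gold_map: np.ndarray):
        p = self.params
        ids, X, P, H, cache, U, Q, Km, prob = self._forward(tokens)
        if prob.shape != gold_map.shape:
            raise RelationError("gold map shape mismatch")
        loss = bce_loss(prob, gold_map)
        n_cells = prob.size
        # d(mean BCE)/d(score) through the sigmoid
        dscore = (prob - gold_map) / (n_cells * np.sqrt(self.config.attn_dim))
        dQ = dscore @ Km
        dKm = dscore.T @ Q
        dU = dQ @ p["Wq"].T + dKm @ p["Wk"].T
        L = len(tokens)
        g = {
            "Wq": U.T @ dQ,
            "Wk": U.T @ dKm,
            "S": dU[L:],
        }
        dUt = dU[:L]
        g["Wt"] = H.T @ dUt
        g["bt"] = dUt.sum(axis=0)
        dH = dUt @ p["Wt"].T
        g_rnn, dP = self.birnn.backward(p, cache, dH)
        g.update(g_rnn)
        g["Wp"] = X.T @ dP
        g["bp"] = dP.sum(axis=0)
        dX = dP @ p["Wp"].T
        gE = np.zeros_like(p["E"])
        np.add.at(gE, ids, dX[:, : self.config.embed_dim])
        g["E"] = gE
        return loss, g

    def predict_document(self, doc: Document):
        """Head-level triples (sentence_index, subj_head, predicate, obj_head)."""
        out = []
        for s in range(doc.n_sentences()):
            toks = doc.sentence_tokens(s)
            if not toks:
                continue
            if len(toks) > self.config.max_sentence_len:
                log.warning(
                    "skipping sentence %d of %s: %d tokens exceeds max %d",
                    s, doc.doc_id, len(toks), self.config.max_sentence_len,
                )
                continue
            for sh, pred, oh in decode_triples(
                self.score_map(toks), self.config.threshold
            ):
                out.append((s, sh, pred, oh))
        return out

    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "vocab": self.lookup.itos,
                "predicates": list(PREDICATES)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **self.params)

    @classmethod
    def load(cls, path) -> "ReModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        config = ReConfig(**meta["config"])
        lookup = LookupEmbedding(meta["vocab"][1:], config.embed_dim)
        model = cls(lookup, config)
        model.params = params
        model.lookup.table = params["E"]
        return model


def _sentence_examples(corpus: list[AnnotatedDocument], max_len: int):
    for ad in corpus:
        by_sent: dict[int, list] = {}
        for r in ad.relations:
            by_sent.setdefault(r.sentence_index, []).append(
                (r.subject.start, r.predicate, r.object.start)
            )
        for s in range(ad.document.n_sentences()):
            toks = ad.document.sentence_tokens(s)
            if not toks:
                continue
            if len(toks) > max_len:
                log.warning(
                    "skipping overlong sentence %d of %s (%d tokens)",
                    s, ad.document.doc_id, len(toks),
                )
                continue
            yield toks, build_gold_interaction_map(len(toks), by_sent.get(s, []))


def train_re(
    corpus: list[AnnotatedDocument],
    config: ReConfig | None = None,
) -> ReModel:
    """Fit the interaction-map scorer with mini-batch Adam on mean BCE.

    Gradients are averaged over ``batch_size`` sentences per step —
    per-sentence steps oscillate on the sparse positive cells.
    Sentences without relations train the negative cells.
    Deterministic for a fixed config seed; raises ``ValueError`` on an
    empty corpus.
    """
    config = config or ReConfig()
    examples = list(_sentence_examples(corpus, config.max_sentence_len))
    if not examples:
        raise ValueError("cannot train on an empty corpus")
    rng = np.random.default_rng(config.seed)
    lookup = LookupEmbedding.from_corpus(
        (toks for toks, _ in examples), config.embed_dim
    )
    model = ReModel(lookup, config)
    model.init_params(rng)
    opt = Adam(model.params, lr=config.lr)
    for _ in range(config.epochs):
        order = rng.permutation(len(examples))
        total = 0.0
        acc: dict[str, np.ndarray] | None = None
        in_batch = 0
        for i in order:
            toks, gold = examples[i]
            loss, grads = model.loss_and_grads(toks, gold)
            total += loss
            if acc is None:
                acc = {k: v.copy() for k, v in grads.items()}
            else:
                for k, v in grads.items():
                    acc[k] += v
            in_batch += 1
            if in_batch == config.batch_size:
                for k in acc:
                    acc[k] /= in_batch
                opt.step(acc)
                acc, in_batch = None, 0
        if acc is not None:
            for k in acc:
                acc[k] /= in_batch
            opt.step(acc)
        model.loss_history.append(total / len(examples))
    return model
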