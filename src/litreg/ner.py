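"""BiRNN-CRF named-entity tagger over BIO tags.

Per-token embeddings (a trainable lookup table merged with fixed
character-window features through a linear layer) feed a bidirectional
tanh RNN; a linear map produces per-tag emission scores and a
linear-chain CRF supplies transition scores. Training minimises the
CRF negative conditional log-likelihood (forward algorithm); decoding
is Viterbi under a hard BIO-validity mask, so output spans are always
well-formed.

All gradients are hand-derived; ``tests`` verify them against finite
differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from litreg import crf
from litreg.corpus import (
    BIO_TAGS,
    TAG_INDEX,
    AnnotatedDocument,
    Document,
    EntitySpan,
    bio_decode,
    bio_encode,
)
from litreg.embeddings import CharWindowEmbedding, LookupEmbedding
from litreg.nn import Adam, BiRNN, glorot


@dataclass
class NerConfig:
    embed_dim: int = 32
    char_dim: int = 24
    proj_dim: int = 48
    hidden: int = 32
    lr: float = 0.01
    epochs: int = 12
    seed: int = 0


def _sentence_examples(corpus: list[AnnotatedDocument]):
    """Yield (tokens, gold tag-id array) per sentence of the corpus."""
    for ad in corpus:
        by_sent: dict[int, list[EntitySpan]] = {}
        for e in ad.entities:
            by_sent.setdefault(e.sentence_index, []).append(e)
        for s in range(ad.document.n_sentences()):
            toks = ad.document.sentence_tokens(s)
            if not toks:
                continue
            tags = bio_encode(by_sent.get(s, []), len(toks))
            yield toks, np.array([TAG_INDEX[t] for t in tags], dtype=np.int64)


class NerModel:
    """Trainable tagger; construct via :func:`train_ner` or :meth:`load`."""

    def __init__(self, lookup: LookupEmbedding, config: NerConfig):
        self.config = config
        self.lookup = lookup
        self.char = CharWindowEmbedding(config.char_dim)
        self.birnn = BiRNN("rnn", config.proj_dim, config.hidden)
        self.tags = BIO_TAGS
        self.params: dict[str, np.ndarray] = {}
        self.mask, self.start_ok = crf.bio_transition_mask(self.tags)
        self.loss_history: list[float] = []

    # -- parameters --------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        d_in = c.embed_dim + c.char_dim
        T = len(self.tags)
        self.params = {
            "E": self.lookup.init_table(rng),
            "Wp": glorot(rng, d_in, c.proj_dim),
            "bp": np.zeros(c.proj_dim),
            "We": glorot(rng, 2 * c.hidden, T),
            "be": np.zeros(T),
            "A": np.zeros((T, T)),
            "a_start": np.zeros(T),
            "a_stop": np.zeros(T),
        }
        self.params.update(self.birnn.init_params(rng))
        self.lookup.table = self.params["E"]

    # -- forward / gradients -----------------------------------------
    def _forward(self, tokens):
        p = self.params
        ids = self.lookup.ids(tokens)
        X = np.concatenate([p["E"][ids], self.char.embed(tokens)], axis=1)
        P = X @ p["Wp"] + p["bp"]
        H, cache = self.birnn.forward(p, P)
        Em = H @ p["We"] + p["be"]
        return ids, X, P, H, cache, Em

    def loss_and_grads(self, tokens, y: np.ndarray):
        """CRF NLL of the gold tags and gradients for every parameter."""
        p = self.params
        ids, X, P, H, cache, Em = self._forward(tokens)
        unary, pairwise, logZ = crf.forward_backward(
            Em, p["A"], p["a_start"], p["a_stop"]
        )
        gold = crf.path_score(Em, p["A"], p["a_start"], p["a_stop"], y)
        nll = logZ - gold
        L, T = Em.shape
        dEm = unary.copy()
        dEm[np.arange(L), y] -= 1.0
        dA = pairwise.sum(axis=0)
        for t in range(1, L):
            dA[y[t - 1], y[t]] -= 1.0
        d_start = unary[0].copy()
        d_start[y[0]] -= 1.0
        d_stop = unary[-1].copy()
        d_stop[y[-1]] -= 1.0

        g = {"A": dA, "a_start": d_start, "a_stop": d_stop}
        g["We"] = H.T @ dEm
        g["be"] = dEm.sum(axis=0)
        dH = dEm @ p["We"].T
        g_rnn, dP = self.birnn.backward(p, cache, dH)
        g.update(g_rnn)
        g["Wp"] = X.T @ dP
        g["bp"] = dP.sum(axis=0)
        dX = dP @ p["Wp"].T
        gE = np.zeros_like(p["E"])
        np.add.at(gE, ids, dX[:, : self.config.embed_dim])
        g["E"] = gE
        return nll, g

    # -- inference ----------------------------------------------------
    def decode_tags(self, tokens) -> list[str]:
        p = self.params
        *_, Em = self._forward(tokens)
        y, _ = crf.viterbi(
            Em, p["A"], p["a_start"], p["a_stop"],
            allowed=self.mask, start_ok=self.start_ok,
        )
        return [self.tags[i] for i in y]

    def predict_document(self, doc: Document) -> list[EntitySpan]:
        """Typed entity spans for every sentence of a tokenized document."""
        out: list[EntitySpan] = []
        for s in range(doc.n_sentences()):
            toks = doc.sentence_tokens(s)
            if not toks:
                continue
            for e in bio_decode(self.decode_tags(toks), sentence_index=s):
                out.append(
                    EntitySpan(
                        e.start, e.end, e.label,
                        surface=doc.token_surface(s, e.start, e.end),
                        sentence_index=s,
                    )
                )
        return out

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab": self.lookup.itos,
            "tags": list(self.tags),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **self.params)

    @classmethod
    def load(cls, path) -> "NerModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        config = NerConfig(**meta["config"])
        lookup = LookupEmbedding(meta["vocab"][1:], config.embed_dim)
        model = cls(lookup, config)
        model.params = params
        model.lookup.table = params["E"]
        return model


def train_ner(
    corpus: list[AnnotatedDocument],
    config: NerConfig | None = None,
) -> NerModel:
    """Fit the tagger by per-sentence Adam on the CRF NLL.

    Deterministic for a fixed config seed. Raises ``ValueError`` on an
    empty corpus (entity labels are validated at corpus load time).
    """
    config = config or NerConfig()
    examples = list(_sentence_examples(corpus))
    if not examples:
        raise ValueError("cannot train on an empty corpus")
    rng = np.random.default_rng(config.seed)
    lookup = LookupEmbedding.from_corpus(
        (toks for toks, _ in examples), config.embed_dim
    )
    model = NerModel(lookup, config)
    model.init_params(rng)
    opt = Adam(model.params, lr=config.lr)
    for _ in range(config.epochs):
        order = rng.permutation(len(examples))
        total = 0.0
        for i in order:
            toks, y = examples[i]
            nll, grads = model.loss_and_grads(toks, y)
            opt.step(grads)
            total += nll
        model.loss_history.append(total / len(examples))
    return model


def predict_entities(model: NerModel, doc: Document) -> list[EntitySpan]:
    return model.predict_document(doc)
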