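"""Pluggable token-embedding providers.

The taggers consume embeddings through a narrow contract —
``dimension`` plus ``embed(tokens) -> L x dimension array`` — so that
contextual embeddings (e.g. transformer models) can be plugged in by
users. Two desk-scale providers ship with the package:

* :class:`LookupEmbedding` — a trainable per-token lookup table built
  from a corpus vocabulary (parameters updated during training);
* :class:`CharWindowEmbedding` — fixed hashed character-n-gram
  features that give unseen tokens (aliases, morphological variants)
  a non-degenerate representation.
"""

from __future__ import annotations

import zlib
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

UNK = "<unk>"


@runtime_checkable
class EmbeddingProvider(Protocol):
    dimension: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


class LookupEmbedding:
    """Trainable lookup table over a closed vocabulary.

    The table itself is owned by the model's parameter dict (so one
    optimizer updates it); this class maps tokens to row ids. Unknown
    tokens fall back to a dedicated ``<unk>`` row. Lookup is
    case-sensitive: case distinguishes gene aliases ("Wnt4" vs "WNT4").
    """

    def __init__(self, vocab: Sequence[str], dimension: int = 32):
        self.dimension = dimension
        self.itos = [UNK] + [t for t in vocab if t != UNK]
        self.stoi = {t: i for i, t in enumerate(self.itos)}
        self.table: np.ndarray | None = None  # bound by the model

    @classmethod
    def from_corpus(cls, sentences: Iterable[Sequence[str]],
                    dimension: int = 32) -> "LookupEmbedding":
        seen: dict[str, None] = {}
        for toks in sentences:
            for t in toks:
                seen.setdefault(t, None)
        return cls(sorted(seen), dimension)

    def init_table(self, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, 0.1, size=(len(self.itos), self.dimension))

    def ids(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.stoi.get(t, 0) for t in tokens], dtype=np.int64)

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if self.table is None:
            raise RuntimeError("lookup table not initialised")
        return self.table[self.ids(tokens)]


class CharWindowEmbedding:
    """Fixed hashed character-trigram features, one vector per token.

    Tokens are padded with boundary markers, every trigram is hashed
    (CRC32, stable across runs and platforms) into ``dimension``
    buckets, and the count vector is L2-normalised. Deterministic and
    untrained; serves as a character-level view alongside the lookup
    table, so morphological variants of one symbol land near each
    other.
    """

    def __init__(self, dimension: int = 24, n: int = 3):
        self.dimension = dimension
        self.n = n

    def _vector(self, token: str) -> np.ndarray:
        s = f"^{token}$"
        v = np.zeros(self.dimension)
        if len(s) < self.n:
            grams = [s]
        else:
            grams = [s[i : i + self.n] for i in range(len(s) - self.n + 1)]
        for g in grams:
            h = zlib.crc32(g.encode("utf-8"))
            # signed hashing decorrelates colliding buckets
            v[h % self.dimension] += -1.0 if (h >> 16) & 1 else 1.0
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self._vector(t) for t in tokens]) if tokens else (
            np.zeros((0, self.dimension))
        )
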