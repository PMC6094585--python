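"""Word-vector tables, averaged phrase embeddings and cosine distance.

A term's embedding is the arithmetic mean of its tokens' word vectors —
the "centre of mass" of the phrase.  All distances in the system are
``dis(u, v) = 1 - cos(u, v)`` in ``[0, 2]``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)


class DegenerateTermError(ValueError):
    """Raised when a phrase has no usable word vectors."""


@dataclass
class WordVectorTable:
    """An indexed set of d-dimensional word vectors.

    ``vocab`` maps each word to its row in ``matrix``; rows are float64.
    """

    vocab: dict[str, int]
    matrix: np.ndarray

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self.vocab[word]]

    def copy(self) -> "WordVectorTable":
        return WordVectorTable(dict(self.vocab), self.matrix.copy())

    def add(self, word: str, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64).reshape(1, -1)
        if vec.shape[1] != self.dim:
            raise ValueError(f"vector of dim {vec.shape[1]} != table dim {self.dim}")
        if word in self.vocab:
            self.matrix[self.vocab[word]] = vec[0]
        else:
            self.vocab[word] = self.matrix.shape[0]
            self.matrix = np.vstack([self.matrix, vec])


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Read word2vec text format: a ``N d`` header then one
    ``word c_1 ... c_d`` row per line.  ``.gz`` paths are decompressed.

    On duplicate words the last occurrence wins (with a warning), matching
    the common text-dialect behaviour.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'N d', got {header!r}")
        n, d = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        rows = np.empty((n, d), dtype=np.float64)
        count = 0
        lines_read = 0
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2 and not line.strip():
                continue
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected 1 word + {d} components, got {len(parts)} fields"
                )
            lines_read += 1
            word = parts[0]
            vec = np.asarray(parts[1:], dtype=np.float64)
            if word in vocab:
                log.warning("%s:%d: duplicate word %r; last occurrence wins", path, lineno, word)
                rows[vocab[word]] = vec
                continue
            if lines_read > n:
                raise ValueError(f"{path}: more rows than header count {n}")
            vocab[word] = count
            rows[count] = vec
            count += 1
    if lines_read != n:
        raise ValueError(f"{path}: header promised {n} rows, found {lines_read}")
    return WordVectorTable(vocab, rows[:count])


def save_word_vectors(table: WordVectorTable, path: str | Path, precision: int = 6) -> None:
    """Write word2vec text format at ``precision`` significant digits."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    words = sorted(table.vocab, key=table.vocab.get)
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {table.dim}\n")
        for w in words:
            comps = " ".join(f"{c:.{precision}g}" for c in table.vector(w))
            fh.write(f"{w} {comps}\n")


def init_oov(words: Sequence[str], dim: int, seed: int) -> dict[str, np.ndarray]:
    """Out-of-vocabulary vectors: each component i.i.d. Normal(0, 0.01).

    Deterministic given the seed (one shared generator, words in given
    order).
    """
    rng = np.random.default_rng(seed)
    return {w: rng.normal(0.0, 0.1, size=dim) for w in words}


def sentence_embedding(
    tokens: Iterable[str],
    table: WordVectorTable,
    oov: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean of the tokens' word vectors (repeats counted with multiplicity).

    ``oov`` optionally supplies vectors for words missing from the table;
    words found in neither are dropped.  Raises
    :class:`DegenerateTermError` when no token has a vector.
    """
    vecs = []
    for t in tokens:
        if t in table.vocab:
            vecs.append(table.vector(t))
        elif oov is not None and t in oov:
            vecs.append(oov[t])
    if not vecs:
        raise DegenerateTermError(f"no word vectors for tokens {list(tokens)!r}")
    return np.mean(vecs, axis=0)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cos(u, v)``, in [0, 2].  Zero vectors are an error (a zero
    vector has no direction; silently returning 1 would hide bugs)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for zero vector")
    c = float(np.dot(u, v) / (nu * nv))
    return 1.0 - max(-1.0, min(1.0, c))
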