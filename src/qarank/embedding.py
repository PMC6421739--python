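"""Double-level (word + character) sentence input matrices.

A sentence enters the encoder as a fixed-length T x d matrix.  Each level
(word tokens, character tokens) is looked up in its own embedding table,
padded with zero vectors or truncated to the target length, and the two
views are combined position-wise as

    Sen = alpha * Sen_word + (1 - alpha) * Sen_character

with alpha = 0.6 by default.  Because the word view is shorter than the
character view, it is aligned to the character length either by trailing
zero vectors ("pad", the default) or by repeating each word's vector
across its constituent characters' positions ("broadcast").  Target
lengths are counted in character positions (defaults: question 50,
answer 70).

The built-in embedding trainer is a deterministic spectral method:
positional co-occurrence counts within a fixed window, PPMI reweighting,
and a truncated SVD factorisation to the requested dimension.  It covers
every token observed in the corpus and is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import QACorpus
from .corpus import Sentence

__all__ = [
    "EmbeddingTable",
    "PaddedSequence",
    "embed_level",
    "double_level_embed",
    "train_token_embeddings",
]


@dataclass
class EmbeddingTable:
    """Token -> fixed-dimension vector map with an out-of-vocabulary
    policy ("zero": zero vector; "hash": deterministic pseudo-random
    vector derived from the token)."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    oov_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.oov_policy not in ("zero", "hash"):
            raise ValueError(f"unknown OOV policy {self.oov_policy!r}")
        for tok, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"token {tok!r}: vector of shape {vec.shape},"
                    f" expected ({self.dimension},)"
                )
            self.vectors[tok] = vec

    def lookup(self, token: str) -> np.ndarray:
        vec = self.vectors.get(token)
        if vec is not None:
            return vec
        if self.oov_policy == "zero":
            return np.zeros(self.dimension)
        rng = np.random.default_rng(zlib.crc32(token.encode("utf-8")))
        return rng.uniform(-0.1, 0.1, self.dimension)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class PaddedSequence:
    """Fixed-length embedded sentence: a T x d matrix plus a validity
    mask; padded positions carry the zero vector."""

    matrix: np.ndarray
    mask: np.ndarray  # bool, True = valid

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.mask.shape != (self.matrix.shape[0],):
            raise ValueError("matrix must be T x d with a length-T mask")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_rows(self) -> np.ndarray:
        return self.matrix[self.mask]


def embed_level(
    tokens: Sequence[str], table: EmbeddingTable, target_len: int
) -> PaddedSequence:
    """Look up, truncate to target_len, and zero-pad one tokenization level."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if len(tokens) == 0:
        raise ValueError("cannot embed an empty token sequence")
    n = min(len(tokens), target_len)
    matrix = np.zeros((target_len, table.dimension))
    for i in range(n):
        matrix[i] = table.lookup(tokens[i])
    mask = np.zeros(target_len, dtype=bool)
    mask[:n] = True
    return PaddedSequence(matrix, mask)


def _broadcast_word_rows(
    tokens: Sequence[str],
    table: EmbeddingTable,
    char_counts: Mapping[str, int],
    target_len: int,
) -> PaddedSequence:
    rows: list[np.ndarray] = []
    for tok in tokens:
        span = char_counts.get(tok, 1)
        vec = table.lookup(tok)
        rows.extend([vec] * span)
        if len(rows) >= target_len:
            break
    n = min(len(rows), target_len)
    matrix = np.zeros((target_len, table.dimension))
    if n:
        matrix[:n] = np.stack(rows[:n])
    mask = np.zeros(target_len, dtype=bool)
    mask[:n] = True
    return PaddedSequence(matrix, mask)


def double_level_embed(
    sentence: Sentence,
    word_table: EmbeddingTable,
    char_table: EmbeddingTable,
    alpha: float = 0.6,
    target_len: int = 50,
    alignment: str = "pad",
    char_counts: Mapping[str, int] | None = None,
) -> PaddedSequence:
    """Combine the word- and character-level views of one sentence.

    With alignment "pad" the word-vector sequence is left-aligned and
    zero-complemented up to the character length; with "broadcast" each
    word's vector is repeated across its characters' positions (requires
    `char_counts`, a token -> span-length map).  The mask is the
    character level's mask in both cases, and the output is exactly
    alpha * W + (1 - alpha) * C at every position.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha!r}")
    if word_table.dimension != char_table.dimension:
        raise ValueError(
            f"table dimension mismatch: word {word_table.dimension},"
            f" character {char_table.dimension}"
        )
    C = embed_level(sentence.char_tokens, char_table, target_len)
    if alignment == "pad":
        W = embed_level(sentence.word_tokens, word_table, target_len)
    elif alignment == "broadcast":
        if char_counts is None:
            raise ValueError("alignment 'broadcast' requires char_counts")
        W = _broadcast_word_rows(
            sentence.word_tokens, word_table, char_counts, target_len
        )
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    matrix = alpha * W.matrix + (1.0 - alpha) * C.matrix
    # padded positions must stay exactly zero
    matrix[~C.mask] = 0.0
    return PaddedSequence(matrix, C.mask.copy())


def _cooccurrence_svd(
    sequences: list[Sequence[str]], dimension: int, window: int
) -> dict[str, np.ndarray]:
    vocab = sorted({t for seq in sequences for t in seq})
    idx = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    counts = np.zeros((n, n))
    for seq in sequences:
        ids = [idx[t] for t in seq]
        for i, a in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    counts[a, ids[j]] += 1.0
    total = counts.sum()
    if total == 0:
        # single-token corpus: no context pairs; fall back to identity rows
        mat = np.eye(n)
    else:
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log((counts * total) / (row @ col))
        mat = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    U, S, _ = np.linalg.svd(mat, full_matrices=False)
    k = min(dimension, n)
    emb = U[:, :k] * np.sqrt(S[:k])
    # fix SVD sign ambiguity: largest-magnitude component of each column positive
    for c in range(k):
        pivot = emb[np.argmax(np.abs(emb[:, c])), c]
        if pivot < 0:
            emb[:, c] = -emb[:, c]
    if k < dimension:
        emb = np.hstack([emb, np.zeros((n, dimension - k))])
    return {t: emb[idx[t]].copy() for t in vocab}


def train_token_embeddings(
    corpus: QACorpus,
    dimension: int = 100,
    window: int = 5,
    seed: int = 0,
) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Train one table per level on all corpus sentences.

    The spectral trainer (co-occurrence, PPMI, truncated SVD) is fully
    deterministic; `seed` is accepted for interface compatibility with
    stochastic trainers and does not affect the result.
    """
    sentences = list(corpus.questions) + list(corpus.answers)
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    word_vecs = _cooccurrence_svd(
        [s.word_tokens for s in sentences], dimension, window
    )
    char_vecs = _cooccurrence_svd(
        [s.char_tokens for s in sentences], dimension, window
    )
    return (
        EmbeddingTable(dimension, word_vecs),
        EmbeddingTable(dimension, char_vecs),
    )
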