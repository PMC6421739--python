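"""Corpus containers, serialization, and the training/evaluation views.

A corpus is a set of questions and candidate answers, each carried as two
parallel tokenizations — a word-level and a character-level view — plus a
relevance relation marking which (question, answer) pairs are correct.

Two derived views drive the pipeline:

* training triples (question, correct answer, wrong answer), the unit of
  the hinge objective, built at a fixed negatives-per-positive ratio with
  negatives sampled uniformly without replacement per question;
* answer pools: per question, all its correct answers plus uniformly
  sampled distinct negatives up to a fixed pool size, the unit of top-k
  retrieval evaluation.

Serialization is JSON Lines, one record per question::

    {"qid": ..., "word_tokens": [...], "char_tokens": [...],
     "answers": [{"aid": ..., "word_tokens": [...], "char_tokens": [...],
                  "label": true|false}, ...],
     "relevant": ["a042", ...]}        # optional cross-record positives

Embedding tables use the word2vec text format: a "count dim" header line
followed by one token and `dim` reals per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CorpusFormatError",
    "Sentence",
    "QACorpus",
    "TrainingTriple",
    "AnswerPool",
    "read_corpus",
    "write_corpus",
    "build_training_triples",
    "build_answer_pools",
    "read_embeddings",
    "write_embeddings",
]


class CorpusFormatError(ValueError):
    """Malformed corpus or embedding file; message names the offending
    line or identifier."""


@dataclass(frozen=True)
class Sentence:
    """One question or answer with both tokenization views."""

    id: str
    word_tokens: tuple[str, ...]
    char_tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.word_tokens or not self.char_tokens:
            raise ValueError(f"sentence {self.id!r}: empty token sequence")
        object.__setattr__(self, "word_tokens", tuple(self.word_tokens))
        object.__setattr__(self, "char_tokens", tuple(self.char_tokens))


@dataclass
class QACorpus:
    """Questions, answers, and the positive (qid, aid) relevance pairs."""

    questions: list[Sentence] = field(default_factory=list)
    answers: list[Sentence] = field(default_factory=list)
    relevance: set[tuple[str, str]] = field(default_factory=set)
    # qid -> aids of the answers serialized under that question's record
    owner: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        qids = [q.id for q in self.questions]
        aids = [a.id for a in self.answers]
        for name, ids in (("question", qids), ("answer", aids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CorpusFormatError(f"duplicate {name} id {i!r}")
                seen.add(i)
        qset, aset = set(qids), set(aids)
        for qid, aid in self.relevance:
            if qid not in qset:
                raise CorpusFormatError(
                    f"relevance pair references unknown question id {qid!r}"
                )
            if aid not in aset:
                raise CorpusFormatError(
                    f"relevance pair references unknown answer id {aid!r}"
                )

    @property
    def question_by_id(self) -> dict[str, Sentence]:
        return {q.id: q for q in self.questions}

    @property
    def answer_by_id(self) -> dict[str, Sentence]:
        return {a.id: a for a in self.answers}

    def positives_of(self, qid: str) -> list[str]:
        """Answer ids relevant to `qid`, in corpus answer order."""
        rel = {a for q, a in self.relevance if q == qid}
        return [a.id for a in self.answers if a.id in rel]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QACorpus):
            return NotImplemented
        return (
            self.questions == other.questions
            and self.answers == other.answers
            and self.relevance == other.relevance
        )


@dataclass(frozen=True)
class TrainingTriple:
    qid: str
    pos_aid: str
    neg_aid: str


@dataclass(frozen=True)
class AnswerPool:
    qid: str
    candidates: tuple[str, ...]
    ground_truth: frozenset[str]

    def __post_init__(self) -> None:
        cands = tuple(self.candidates)
        object.__setattr__(self, "candidates", cands)
        object.__setattr__(self, "ground_truth", frozenset(self.ground_truth))
        if len(set(cands)) != len(cands):
            raise ValueError(f"pool for {self.qid!r}: duplicate candidates")
        if not self.ground_truth:
            raise ValueError(f"pool for {self.qid!r}: empty ground truth")
        if not self.ground_truth <= set(cands):
            raise ValueError(
                f"pool for {self.qid!r}: ground truth not contained in candidates"
            )


# ---------------------------------------------------------------------------
# corpus serialization


def _require(record: Mapping, key: str, lineno: int):
    if key not in record:
        raise CorpusFormatError(f"line {lineno}: missing field {key!r}")
    return record[key]


def read_corpus(path) -> QACorpus:
    """Parse a JSON Lines corpus file; malformed lines are reported with
    their line number, dangling relevance references with the id."""
    questions: list[Sentence] = []
    answers: list[Sentence] = []
    relevance: set[tuple[str, str]] = set()
    owner: dict[str, list[str]] = {}
    deferred: list[tuple[str, str]] = []  # cross-record "relevant" entries
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})")
            qid = str(_require(rec, "qid", lineno))
            try:
                q = Sentence(
                    qid,
                    tuple(_require(rec, "word_tokens", lineno)),
                    tuple(_require(rec, "char_tokens", lineno)),
                )
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}")
            questions.append(q)
            owner[qid] = []
            for ans in _require(rec, "answers", lineno):
                aid = str(_require(ans, "aid", lineno))
                try:
                    a = Sentence(
                        aid,
                        tuple(_require(ans, "word_tokens", lineno)),
                        tuple(_require(ans, "char_tokens", lineno)),
                    )
                except ValueError as exc:
                    raise CorpusFormatError(f"line {lineno}: {exc}")
                answers.append(a)
                owner[qid].append(aid)
                if _require(ans, "label", lineno):
                    relevance.add((qid, aid))
            for aid in rec.get("relevant", []):
                deferred.append((qid, str(aid)))
    known_aids = {a.id for a in answers}
    for qid, aid in deferred:
        if aid not in known_aids:
            raise CorpusFormatError(
                f"relevance pair references unknown answer id {aid!r}"
                f" (question {qid!r})"
            )
        relevance.add((qid, aid))
    return QACorpus(questions, answers, relevance, owner)


def write_corpus(corpus: QACorpus, path) -> None:
    """Write JSON Lines; inverse of read_corpus."""
    owner = corpus.owner
    if not owner or set(owner) != {q.id for q in corpus.questions}:
        # answers without recorded ownership are attached to the first question
        owner = {q.id: [] for q in corpus.questions}
        if corpus.questions:
            owner[corpus.questions[0].id] = [a.id for a in corpus.answers]
    abyid = corpus.answer_by_id
    owned = {aid: qid for qid, aids in owner.items() for aid in aids}
    with open(path, "w", encoding="utf-8") as fh:
        for q in corpus.questions:
            recs = []
            for aid in owner.get(q.id, []):
                a = abyid[aid]
                recs.append(
                    {
                        "aid": a.id,
                        "word_tokens": list(a.word_tokens),
                        "char_tokens": list(a.char_tokens),
                        "label": (q.id, a.id) in corpus.relevance,
                    }
                )
            rec = {
                "qid": q.id,
                "word_tokens": list(q.word_tokens),
                "char_tokens": list(q.char_tokens),
                "answers": recs,
            }
            extra = sorted(
                aid
                for qq, aid in corpus.relevance
                if qq == q.id and owned.get(aid) != q.id
            )
            if extra:
                rec["relevant"] = extra
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# training triples and answer pools


def build_training_triples(
    corpus: QACorpus,
    negatives_per_positive: int = 5,
    seed: int = 0,
) -> list[TrainingTriple]:
    """One triple per (positive pair, sampled negative).

    For each relevance pair (q, a+), `negatives_per_positive` negatives are
    drawn uniformly without replacement from the answers not positive for
    q.  Sampling is per question without replacement but independent
    across questions; deterministic under `seed`.
    """
    if negatives_per_positive < 0:
        raise ValueError("negatives_per_positive must be >= 0")
    rng = np.random.default_rng(seed)
    all_aids = [a.id for a in corpus.answers]
    triples: list[TrainingTriple] = []
    for q in corpus.questions:
        positives = corpus.positives_of(q.id)
        if not positives:
            raise ValueError(f"question {q.id!r} has no positive answer")
        pos_set = set(positives)
        negatives = [a for a in all_aids if a not in pos_set]
        for pos in positives:
            if negatives_per_positive == 0:
                continue
            if len(negatives) < negatives_per_positive:
                raise ValueError(
                    f"question {q.id!r}: {len(negatives)} non-positive answers"
                    f" available, {negatives_per_positive} required"
                )
            picks = rng.choice(
                len(negatives), size=negatives_per_positive, replace=False
            )
            for k in picks:
                triples.append(TrainingTriple(q.id, pos, negatives[int(k)]))
    return triples


def build_answer_pools(
    corpus: QACorpus,
    pool_size: int = 100,
    seed: int = 0,
) -> list[AnswerPool]:
    """One pool per question: all its positives plus uniformly sampled
    distinct negatives up to `pool_size`."""
    rng = np.random.default_rng(seed)
    all_aids = [a.id for a in corpus.answers]
    if pool_size > len(all_aids):
        raise ValueError(
            f"pool_size {pool_size} exceeds corpus answer count {len(all_aids)}"
        )
    pools: list[AnswerPool] = []
    for q in corpus.questions:
        positives = corpus.positives_of(q.id)
        if not positives:
            raise ValueError(f"question {q.id!r} has no positive answer")
        if pool_size < len(positives):
            raise ValueError(
                f"question {q.id!r}: pool_size {pool_size} smaller than its"
                f" {len(positives)} positives"
            )
        pos_set = set(positives)
        negatives = [a for a in all_aids if a not in pos_set]
        n_neg = pool_size - len(positives)
        picks = rng.choice(len(negatives), size=n_neg, replace=False)
        cands = list(positives) + [negatives[int(k)] for k in picks]
        pools.append(AnswerPool(q.id, tuple(cands), frozenset(pos_set)))
    return pools


def write_pools(pools: Iterable[AnswerPool], path) -> None:
    """JSON Lines, one pool per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pools:
            fh.write(
                json.dumps(
                    {
                        "qid": p.qid,
                        "candidates": list(p.candidates),
                        "ground_truth": sorted(p.ground_truth),
                    }
                )
                + "\n"
            )


def read_pools(path) -> list[AnswerPool]:
    pools: list[AnswerPool] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                pools.append(
                    AnswerPool(
                        rec["qid"],
                        tuple(rec["candidates"]),
                        frozenset(rec["ground_truth"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}")
    return pools


# ---------------------------------------------------------------------------
# embedding table serialization (word2vec text format)


def read_embeddings(path) -> "EmbeddingTable":
    """Parse a word2vec-text embedding file into an EmbeddingTable."""
    from .embedding import EmbeddingTable

    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError("line 1: expected header 'count dim'")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise CorpusFormatError("line 1: non-integer header fields")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            token, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise CorpusFormatError(
                    f"line {lineno}: expected {dim} values, got {len(vals)}"
                )
            if token in vectors:
                raise CorpusFormatError(f"line {lineno}: duplicate token {token!r}")
            vectors[token] = np.array([float(v) for v in vals])
    if len(vectors) != count:
        raise CorpusFormatError(
            f"header announces {count} tokens, file contains {len(vectors)}"
        )
    return EmbeddingTable(dimension=dim, vectors=vectors)


def write_embeddings(table, path) -> None:
    """Write word2vec text format; floats use shortest round-trip repr so
    write -> read -> write is byte-stable."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for token, vec in table.vectors.items():
            vals = " ".join(repr(float(v)) for v in vec)
            fh.write(f"{token} {vals}\n")
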