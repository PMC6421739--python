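"""Synthetic Q&A corpora with controllable retrieval signal.

The generator emulates the structure of a pool-based answer-selection
corpus without any natural language: words are opaque symbols ("w017"),
each composed of a fixed number of character symbols ("c04").  The word
inventory is partitioned into disjoint topics; every question draws its
words from one topic, and each of its correct answers draws a
controllable fraction (`overlap_rate`) of its word tokens from the
question's own realized tokens (hence from its topic), the remainder
coming from other topics.  Because topics are disjoint, `overlap_rate`
is an exact, testable quantity rather than a tendency; because the
overlap words come from the question itself, a correct answer stays
identifiable even among answers of other same-topic questions, keeping
the retrieval signal learnable at any number of topics.

A separate word-segmentation-noise process degrades the word-level view:
each word token is, independently with a given probability, replaced by
its constituent character tokens, while the character-level view stays
intact — mimicking the segmentation errors that motivate combining
word- and character-level embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import QACorpus, Sentence

__all__ = [
    "ConfigurationError",
    "SynthConfig",
    "Vocabulary",
    "generate_vocabulary",
    "generate_corpus",
    "inject_segmentation_noise",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; identical configs produce identical corpora.

    Lengths are word-token counts before padding; `overlap_rate` is the
    fraction of a correct answer's words drawn from its question's topic;
    `segmentation_noise_rate` the probability a word token is replaced by
    its characters in the word-level view.
    """

    n_topics: int = 10
    words_per_topic: int = 20
    chars_per_word: int = 2
    n_questions: int = 200
    answers_per_question_pos: int = 2
    question_len: int = 50
    answer_len: int = 70
    overlap_rate: float = 0.8
    segmentation_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_topics": self.n_topics,
            "words_per_topic": self.words_per_topic,
            "chars_per_word": self.chars_per_word,
            "n_questions": self.n_questions,
            "answers_per_question_pos": self.answers_per_question_pos,
            "question_len": self.question_len,
            "answer_len": self.answer_len,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name, v in (
            ("overlap_rate", self.overlap_rate),
            ("segmentation_noise_rate", self.segmentation_noise_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class Vocabulary:
    """Word inventory with per-word character decompositions and the
    disjoint topic partition."""

    words: dict[str, tuple[str, ...]]  # word -> character decomposition
    topics: tuple[tuple[str, ...], ...]
    chars: tuple[str, ...]

    def char_counts(self) -> dict[str, int]:
        """Token -> number of character positions it occupies (words map
        to their decomposition length, bare characters to 1)."""
        counts = {w: len(d) for w, d in self.words.items()}
        counts.update({c: 1 for c in self.chars})
        return counts


def generate_vocabulary(cfg: SynthConfig) -> Vocabulary:
    """Create n_topics * words_per_topic distinct words, each a distinct
    tuple of chars_per_word characters from a shared inventory."""
    rng = np.random.default_rng([cfg.seed, 1])
    total = cfg.n_topics * cfg.words_per_topic
    n_chars = max(2, math.ceil(total ** (1.0 / cfg.chars_per_word)) + 1)
    chars = tuple(f"c{i:03d}" for i in range(n_chars))
    decomps: set[tuple[str, ...]] = set()
    words: dict[str, tuple[str, ...]] = {}
    for i in range(total):
        while True:
            d = tuple(
                chars[int(k)] for k in rng.integers(0, n_chars, cfg.chars_per_word)
            )
            if d not in decomps:
                break
        decomps.add(d)
        words[f"w{i:04d}"] = d
    order = list(words)
    rng.shuffle(order)
    topics = tuple(
        tuple(order[t * cfg.words_per_topic : (t + 1) * cfg.words_per_topic])
        for t in range(cfg.n_topics)
    )
    return Vocabulary(words=words, topics=topics, chars=chars)


def _make_sentence(sid: str, word_seq: list[str], vocab: Vocabulary) -> Sentence:
    chars = tuple(c for w in word_seq for c in vocab.words[w])
    return Sentence(sid, tuple(word_seq), chars)


def generate_corpus(cfg: SynthConfig, vocab: Vocabulary) -> QACorpus:
    """Generate questions with question-overlapping positives.

    Each question draws its words from one topic; each of its
    `answers_per_question_pos` correct answers draws round(overlap_rate *
    answer_len) words from the question's own tokens and the rest
    uniformly from the other topics.  All randomness comes from one
    stream seeded by cfg.seed, consumed in question order.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n_overlap = round(cfg.overlap_rate * cfg.answer_len)
    if n_overlap < cfg.answer_len and cfg.n_topics < 2:
        raise ConfigurationError(
            "overlap_rate < 1 requires at least 2 topics to draw"
            " non-topic words from"
        )
    questions: list[Sentence] = []
    answers: list[Sentence] = []
    relevance: set[tuple[str, str]] = set()
    owner: dict[str, list[str]] = {}
    aid_counter = 0
    all_words = list(vocab.words)
    topic_sets = [set(t) for t in vocab.topics]
    for qi in range(cfg.n_questions):
        t = int(rng.integers(cfg.n_topics))
        topic = vocab.topics[t]
        other = [w for w in all_words if w not in topic_sets[t]]
        qid = f"q{qi:05d}"
        q_words = [topic[int(k)] for k in rng.integers(0, len(topic), cfg.question_len)]
        questions.append(_make_sentence(qid, q_words, vocab))
        owner[qid] = []
        for _ in range(cfg.answers_per_question_pos):
            in_topic = [
                q_words[int(k)] for k in rng.integers(0, len(q_words), n_overlap)
            ]
            n_out = cfg.answer_len - n_overlap
            out_topic = (
                [other[int(k)] for k in rng.integers(0, len(other), n_out)]
                if n_out
                else []
            )
            a_words = in_topic + out_topic
            rng.shuffle(a_words)
            aid = f"a{aid_counter:05d}"
            aid_counter += 1
            answers.append(_make_sentence(aid, a_words, vocab))
            owner[qid].append(aid)
            relevance.add((qid, aid))
    return QACorpus(questions, answers, relevance, owner)


def _noisy_sentence(s: Sentence, rate: float, rng: np.random.Generator) -> Sentence:
    n_w, n_c = len(s.word_tokens), len(s.char_tokens)
    if n_c % n_w != 0:
        raise ValueError(
            f"sentence {s.id!r}: character view not evenly aligned to words"
        )
    k = n_c // n_w
    out: list[str] = []
    for i, w in enumerate(s.word_tokens):
        if rng.random() < rate:
            out.extend(s.char_tokens[i * k : (i + 1) * k])
        else:
            out.append(w)
    return Sentence(s.id, tuple(out), s.char_tokens)


def inject_segmentation_noise(
    corpus: QACorpus, rate: float, seed: int = 0
) -> QACorpus:
    """Return a copy in which each word token has independently been
    replaced, with probability `rate`, by its character tokens in the
    word-level view.  Character-level views are untouched; the input
    corpus is not modified.

    Requires the uniform word->character alignment of generated corpora
    (every word of a sentence decomposes into the same number of
    characters).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"noise rate must lie in [0, 1], got {rate!r}")
    rng = np.random.default_rng([seed, 3])
    questions = [_noisy_sentence(s, rate, rng) for s in corpus.questions]
    answers = [_noisy_sentence(s, rate, rng) for s in corpus.answers]
    return QACorpus(
        questions, answers, set(corpus.relevance), dict(corpus.owner)
    )
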