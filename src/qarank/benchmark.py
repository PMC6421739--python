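"""The seeded synthetic ranking benchmark.

A self-contained, desk-scale study on generated data: 10 disjoint
topics, 200 training questions with 2 correct answers each, 50 held-out
test questions with 1 correct answer each, evaluation pools of 10
candidates (chance top-1 = 0.10), lexical overlap 0.8 between a correct
answer and its question's topic.  The model is scaled to the data:
16-dimensional embeddings, one Bi-LSTM layer of 16 hidden units,
alpha = 0.6, theta1 = 0.6, margin 0.1, Adam at 0.01, batch 50, 30
epochs.  Sentence lengths are 8 words per question and 10 per answer
(two characters per word, so 16/20 character positions).

`run_benchmark` reports the untrained and trained test evaluations, the
training history, and is bit-reproducible under its seed.  An optional
word-segmentation-noise rate degrades the word-level view of both
corpora, which is the setting used to compare the double-level input
(alpha = 0.6) against a word-only input (alpha = 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import Config, EmbedConfig, ModelConfig, TrainConfig
from .corpus import build_answer_pools, build_training_triples
from .embedding import train_token_embeddings
from .model import ModelParams, init_model_params
from .similarity import SimilarityConfig
from .synth import SynthConfig, generate_corpus, generate_vocabulary, inject_segmentation_noise
from .train_eval import (
    EvalReport,
    Featurizer,
    Scorer,
    TrainingHistory,
    evaluate,
    train,
)

__all__ = ["BenchmarkResult", "benchmark_config", "run_benchmark"]

POOL_SIZE = 10


@dataclass
class BenchmarkResult:
    config: Config
    untrained: EvalReport
    trained: EvalReport
    history: TrainingHistory
    chance_top1: float
    model: ModelParams

    @property
    def final_loss(self) -> float:
        return self.history.records[-1].loss


def benchmark_config(seed: int = 0, alpha: float = 0.6, epochs: int = 30) -> Config:
    """The benchmark's study conditions as a full configuration."""
    return Config(
        embedding=EmbedConfig(
            dimension=16, window=5, alpha=alpha, question_len=16, answer_len=20
        ),
        model=ModelConfig(hidden=16, n_layers=1, dropout=0.5, seed=seed),
        similarity=SimilarityConfig(theta1=0.6, margin=0.1),
        train=TrainConfig(batch_size=50, epochs=epochs, learning_rate=0.01, seed=seed),
        synth=SynthConfig(
            n_topics=10,
            words_per_topic=20,
            chars_per_word=2,
            n_questions=200,
            answers_per_question_pos=2,
            question_len=8,
            answer_len=10,
            overlap_rate=0.8,
            seed=seed,
        ),
    )


def run_benchmark(
    seed: int = 0,
    alpha: float = 0.6,
    noise_rate: float = 0.0,
    epochs: int = 30,
) -> BenchmarkResult:
    """Generate the corpora, train embeddings and the model, and
    evaluate on the held-out pools before and after training."""
    cfg = benchmark_config(seed=seed, alpha=alpha, epochs=epochs)
    vocab = generate_vocabulary(cfg.synth)
    train_corpus = generate_corpus(cfg.synth, vocab)
    test_corpus = generate_corpus(
        replace(cfg.synth, n_questions=50, answers_per_question_pos=1, seed=seed + 1),
        vocab,
    )
    if noise_rate > 0:
        train_corpus = inject_segmentation_noise(train_corpus, noise_rate, seed + 2)
        test_corpus = inject_segmentation_noise(test_corpus, noise_rate, seed + 3)

    word_table, char_table = train_token_embeddings(
        train_corpus, dimension=cfg.embedding.dimension, window=cfg.embedding.window
    )
    triples = build_training_triples(train_corpus, 5, seed=seed + 4)
    train_pools = build_answer_pools(train_corpus, POOL_SIZE, seed=seed + 5)
    test_pools = build_answer_pools(test_corpus, POOL_SIZE, seed=seed + 6)

    feat_train = Featurizer(train_corpus, word_table, char_table, cfg.embedding)
    feat_test = Featurizer(test_corpus, word_table, char_table, cfg.embedding)

    model = init_model_params(
        cfg.embedding.dimension,
        cfg.model.hidden,
        cfg.model.n_layers,
        cfg.model.dropout,
        cfg.model.seed,
        cfg.model.init_scale,
    )
    untrained = evaluate(
        test_pools, Scorer(feat_test, cfg.similarity, model, cfg.model)
    )
    model, history = train(
        train_corpus,
        triples,
        word_table,
        char_table,
        cfg,
        eval_pools=train_pools,
        model=model,
        feat=feat_train,
    )
    trained = evaluate(
        test_pools, Scorer(feat_test, cfg.similarity, model, cfg.model)
    )
    return BenchmarkResult(
        config=cfg,
        untrained=untrained,
        trained=trained,
        history=history,
        chance_top1=1.0 / POOL_SIZE,
        model=model,
    )
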