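"""Training loop, pool scoring, and the evaluation battery."""

import numpy as np
import pytest

from qarank.config import Config, EmbedConfig, ModelConfig, TrainConfig
from qarank.corpus import AnswerPool, TrainingTriple, build_training_triples
from qarank.model import flatten_params, init_model_params, load_checkpoint, save_checkpoint
from qarank.similarity import SimilarityConfig
from qarank.train_eval import (
    EvalReport,
    HistoryRecord,
    Scorer,
    TrainingHistory,
    evaluate,
    score_pool,
    steps_to_threshold,
    train,
    triple_batch_loss,
)


def fixed_scorer(rankings):
    """A callable scorer returning prescribed rankings per qid."""
    return lambda pool: rankings[pool.qid]


class TestEvaluate:
    # Three pools with hand-prescribed rankings placing the single
    # positive at ranks 1, 2 and 4 respectively.
    POOLS = [
        AnswerPool("q0", ("a0", "a1", "a2", "a3"), {"a0"}),
        AnswerPool("q1", ("b0", "b1", "b2", "b3"), {"b1"}),
        AnswerPool("q2", ("c0", "c1", "c2", "c3"), {"c3"}),
    ]
    RANKINGS = {
        "q0": [("a0", 0.9), ("a1", 0.5), ("a2", 0.3), ("a3", 0.1)],
        "q1": [("b0", 0.8), ("b1", 0.7), ("b2", 0.2), ("b3", 0.1)],
        "q2": [("c0", 0.9), ("c1", 0.8), ("c2", 0.7), ("c3", 0.6)],
    }

    def test_hand_counted_metrics(self):
        rep = evaluate(self.POOLS, fixed_scorer(self.RANKINGS))
        # positives at ranks 1, 2, 4 -> top1 = 1/3, top2 = 2/3, top3 = 2/3
        assert rep.top1 == pytest.approx(1 / 3)
        assert rep.top2 == pytest.approx(2 / 3)
        assert rep.top3 == pytest.approx(2 / 3)
        # one correct top-1 call out of 3 pools, 3 positives total
        assert rep.precision == pytest.approx(1 / 3)
        assert rep.recall == pytest.approx(1 / 3)
        assert rep.f1 == pytest.approx(1 / 3)

    def test_recall_denominator_counts_all_positives(self):
        pools = [AnswerPool("q0", ("a0", "a1", "a2"), {"a0", "a1"})]
        rankings = {"q0": [("a0", 0.9), ("a1", 0.8), ("a2", 0.1)]}
        rep = evaluate(pools, fixed_scorer(rankings))
        assert rep.top1 == 1.0
        assert rep.precision == 1.0
        assert rep.recall == pytest.approx(0.5)  # 1 hit / 2 positives
        assert rep.f1 == pytest.approx(2 / 3)

    def test_all_wrong_gives_zero_f1(self):
        pools = [AnswerPool("q0", ("a0", "a1"), {"a1"})]
        rankings = {"q0": [("a0", 0.9), ("a1", 0.1)]}
        rep = evaluate(pools, fixed_scorer(rankings))
        assert rep.top1 == 0.0
        assert rep.f1 == 0.0

    def test_empty_pool_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], fixed_scorer({}))


class TestHistory:
    def test_steps_must_increase(self):
        h = TrainingHistory()
        h.append(HistoryRecord(1, 0.5))
        with pytest.raises(ValueError):
            h.append(HistoryRecord(1, 0.4))

    def test_steps_to_threshold_first_crossing(self):
        h = TrainingHistory()
        for step, acc in [(1, None), (2, 0.2), (3, 0.5), (4, 0.9)]:
            h.append(HistoryRecord(step, 1.0, acc))
        assert steps_to_threshold(h, 0.5) == 3
        assert steps_to_threshold(h, 0.21) == 3
        assert steps_to_threshold(h, 0.95) is None

    def test_steps_to_threshold_empty_history_rejected(self):
        with pytest.raises(ValueError):
            steps_to_threshold(TrainingHistory(), 0.5)

    def test_eval_report_rejects_non_nested_topk(self):
        with pytest.raises(ValueError):
            EvalReport(0.9, 0.5, 1.0, 0.9, 0.9, 0.9, {})


class TestScorePool:
    def test_sorted_descending_with_id_tiebreak(self, tiny_featurizer):
        sim = SimilarityConfig(theta1=0.6, margin=0.1)
        pool = AnswerPool("q0", ("a0", "a1", "a2", "a3"), {"a0"})
        ranked = score_pool(None, sim, pool, tiny_featurizer)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        for (aid1, s1), (aid2, s2) in zip(ranked, ranked[1:]):
            if s1 == s2:
                assert aid1 < aid2

    def test_untrained_scores_hand_composed(self, tiny_featurizer):
        """Untrained joint score = theta1 * semantic + theta2 * cosine of
        the mean double-level embedding rows."""
        sim = SimilarityConfig(theta1=0.6, margin=0.1)
        pool = AnswerPool("q0", ("a0", "a1"), {"a0"})
        ranked = dict(score_pool(None, sim, pool, tiny_featurizer))
        for aid in ("a0", "a1"):
            u = tiny_featurizer.qseq["q0"].valid_rows().mean(axis=0)
            v = tiny_featurizer.aseq[aid].valid_rows().mean(axis=0)
            cos = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            want = 0.6 * tiny_featurizer.semantic("q0", aid) + 0.4 * cos
            assert ranked[aid] == pytest.approx(want, rel=1e-12)

    def test_missing_candidate_rejected(self, tiny_featurizer):
        sim = SimilarityConfig()
        pool = AnswerPool("q0", ("a0", "zzz"), {"a0"})
        with pytest.raises(KeyError, match="zzz"):
            score_pool(None, sim, pool, tiny_featurizer)

    def test_model_without_config_rejected(self, tiny_featurizer):
        model = init_model_params(3, hidden=2, n_layers=1, dropout=0.0, seed=0)
        with pytest.raises(ValueError):
            Scorer(tiny_featurizer, SimilarityConfig(), model, None)

    def test_trained_mode_deterministic(self, tiny_featurizer, tiny_model_cfg):
        model = init_model_params(3, hidden=2, n_layers=2, dropout=0.5, seed=0)
        sim = SimilarityConfig()
        pool = AnswerPool("q0", ("a0", "a1", "a2"), {"a0"})
        r1 = score_pool(model, sim, pool, tiny_featurizer, tiny_model_cfg)
        r2 = score_pool(model, sim, pool, tiny_featurizer, tiny_model_cfg)
        assert r1 == r2


class TestTripleBatchLoss:
    def _model(self):
        return init_model_params(3, hidden=2, n_layers=1, dropout=0.0, seed=3)

    def test_satisfied_margin_gives_zero_loss_and_gradient(
        self, tiny_featurizer, tiny_model_cfg
    ):
        """A triple whose positive already outranks its negative by more
        than the margin contributes neither loss nor gradient."""
        model = self._model()
        cfg = ModelConfig(hidden=2, n_layers=1, dropout=0.0, seed=3)
        # order the two candidate answers by their joint similarity
        probe = SimilarityConfig(theta1=0.6, margin=0.1)
        _, losses_a, _ = triple_batch_loss(
            model, tiny_featurizer, [TrainingTriple("q0", "a0", "a1")], probe, cfg,
            compute_grads=False,
        )
        better, worse = ("a0", "a1") if losses_a[0] < probe.margin else ("a1", "a0")
        sim = SimilarityConfig(theta1=0.6, margin=1e-9)
        loss, losses, grads = triple_batch_loss(
            model, tiny_featurizer, [TrainingTriple("q0", better, worse)], sim, cfg
        )
        assert loss == 0.0
        assert all(np.all(g == 0.0) for g in grads.values())

    def test_loss_is_mean_of_per_triple_hinges(self, tiny_featurizer):
        model = self._model()
        cfg = ModelConfig(hidden=2, n_layers=1, dropout=0.0, seed=3)
        batch = [
            TrainingTriple("q0", "a0", "a1"),
            TrainingTriple("q1", "a1", "a2"),
        ]
        loss, losses, _ = triple_batch_loss(
            model, tiny_featurizer, batch, SimilarityConfig(), cfg,
            compute_grads=False,
        )
        assert loss == pytest.approx(float(np.mean(losses)))
        assert np.all(losses >= 0.0)

    def test_semantic_only_config_has_zero_gradient(self, tiny_featurizer):
        """theta1 = 1 removes the text term, so no parameter receives
        gradient regardless of the margin state."""
        model = self._model()
        cfg = ModelConfig(hidden=2, n_layers=1, dropout=0.0, seed=3)
        sim = SimilarityConfig(theta1=1.0, margin=0.5)
        loss, _, grads = triple_batch_loss(
            model, tiny_featurizer, [TrainingTriple("q0", "a0", "a1")], sim, cfg
        )
        assert all(np.all(g == 0.0) for g in grads.values())


def small_training_setup(tmp_path=None):
    """A 6-question corpus and config small enough for subsecond training."""
    from qarank.embedding import train_token_embeddings
    from qarank.synth import SynthConfig, generate_corpus, generate_vocabulary

    scfg = SynthConfig(
        n_topics=3,
        words_per_topic=6,
        chars_per_word=2,
        n_questions=6,
        answers_per_question_pos=2,
        question_len=4,
        answer_len=5,
        overlap_rate=0.8,
        seed=9,
    )
    corpus = generate_corpus(scfg, generate_vocabulary(scfg))
    wt, ct = train_token_embeddings(corpus, dimension=4, window=3)
    cfg = Config(
        embedding=EmbedConfig(dimension=4, alpha=0.6, question_len=8, answer_len=10),
        model=ModelConfig(hidden=3, n_layers=1, dropout=0.5, seed=9),
        similarity=SimilarityConfig(theta1=0.6, margin=0.1),
        train=TrainConfig(batch_size=4, epochs=2, learning_rate=0.01, seed=9),
        synth=scfg,
    )
    triples = build_training_triples(corpus, 3, seed=9)
    return corpus, wt, ct, cfg, triples


class TestTrain:
    def test_deterministic_under_seed(self):
        corpus, wt, ct, cfg, triples = small_training_setup()
        m1, h1 = train(corpus, triples, wt, ct, cfg)
        m2, h2 = train(corpus, triples, wt, ct, cfg)
        f1, f2 = flatten_params(m1), flatten_params(m2)
        for k in f1:
            np.testing.assert_array_equal(f1[k], f2[k])
        assert h1.to_rows() == h2.to_rows()

    def test_different_seed_changes_outcome(self):
        from dataclasses import replace

        corpus, wt, ct, cfg, triples = small_training_setup()
        cfg2 = replace(cfg, train=replace(cfg.train, seed=10))
        m1, _ = train(corpus, triples, wt, ct, cfg)
        m2, _ = train(corpus, triples, wt, ct, cfg2)
        f1, f2 = flatten_params(m1), flatten_params(m2)
        assert any(np.any(f1[k] != f2[k]) for k in f1)

    def test_does_not_mutate_passed_model(self):
        corpus, wt, ct, cfg, triples = small_training_setup()
        model0 = init_model_params(4, 3, 1, 0.5, 9)
        before = {k: v.copy() for k, v in flatten_params(model0).items()}
        train(corpus, triples, wt, ct, cfg, model=model0)
        after = flatten_params(model0)
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_history_cadence_and_train_top1(self):
        from qarank.corpus import build_answer_pools

        corpus, wt, ct, cfg, triples = small_training_setup()
        pools = build_answer_pools(corpus, 4, seed=9)
        model, hist = train(corpus, triples, wt, ct, cfg, eval_pools=pools)
        steps_per_epoch = (len(triples) + cfg.train.batch_size - 1) // cfg.train.batch_size
        assert len(hist.records) == cfg.train.epochs * steps_per_epoch
        evaluated = [r for r in hist.records if r.train_top1 is not None]
        assert len(evaluated) == cfg.train.epochs  # once per epoch by default
        assert all(0.0 <= r.train_top1 <= 1.0 for r in evaluated)

    def test_checkpoint_reproduces_scores(self, tmp_path):
        corpus, wt, ct, cfg, triples = small_training_setup()
        model, _ = train(corpus, triples, wt, ct, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, cfg.to_dict())
        loaded, meta = load_checkpoint(path)
        feat_cfg = cfg.embedding
        from qarank.train_eval import Featurizer

        feat = Featurizer(corpus, wt, ct, feat_cfg)
        pool = AnswerPool(
            corpus.questions[0].id,
            tuple(a.id for a in corpus.answers[:4]),
            {corpus.owner[corpus.questions[0].id][0]},
        )
        r1 = score_pool(model, cfg.similarity, pool, feat, cfg.model)
        r2 = score_pool(loaded, cfg.similarity, pool, feat, cfg.model)
        assert r1 == r2
        assert meta["model"]["hidden"] == 3
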