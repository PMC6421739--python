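"""Margin training over triples and pool-based retrieval evaluation.

Training minimises the mean hinge loss

    L = max(0, M - Sim(q, a+) + Sim(q, a-))

over (question, positive, negative) triples with a first-order optimiser
(Adam by default).  The semantic term of the joint similarity is a
function of the fixed embedding tables only, so it is precomputed per
triple and contributes no gradient; gradients flow through the cosine of
the pooled encoder representations.

Evaluation ranks each question's answer pool by the joint similarity and
reports top-1/2/3 accuracy plus precision, recall and F1 of the top-1
retrieval: each pool's best-ranked candidate is one positive call;
precision is the fraction of calls hitting ground truth, recall the
fraction of all ground-truth pairs retrieved, F1 their harmonic mean.
Ties in ranking are broken by candidate id ascending for determinism.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .corpus import AnswerPool, QACorpus, TrainingTriple
from .embedding import EmbeddingTable, PaddedSequence, double_level_embed
from .model import (
    ModelParams,
    _attention_backward_batch,
    _attention_forward_batch,
    attention_query,
    encode_backward_batch,
    encode_batch,
    flatten_params,
    init_model_params,
    pool_backward_batch,
    pool_batch,
    zero_grads,
)
from .similarity import SimilarityConfig, semantic_similarity

__all__ = [
    "Featurizer",
    "Scorer",
    "HistoryRecord",
    "TrainingHistory",
    "EvalReport",
    "triple_batch_loss",
    "train",
    "score_pool",
    "evaluate",
    "steps_to_threshold",
]


# ---------------------------------------------------------------------------
# featurization


class Featurizer:
    """Precomputed per-sentence inputs: double-level padded matrices,
    per-question attention queries, and the token-vector sets feeding the
    semantic similarity term."""

    def __init__(
        self,
        corpus: QACorpus,
        word_table: EmbeddingTable,
        char_table: EmbeddingTable,
        embed_cfg,
        char_counts=None,
    ):
        self.corpus = corpus
        self.cfg = embed_cfg
        word_table.oov_policy = embed_cfg.oov_policy
        char_table.oov_policy = embed_cfg.oov_policy
        kw = dict(
            word_table=word_table,
            char_table=char_table,
            alpha=embed_cfg.alpha,
            alignment=embed_cfg.alignment,
            char_counts=char_counts,
        )
        self.qseq: dict[str, PaddedSequence] = {
            q.id: double_level_embed(q, target_len=embed_cfg.question_len, **kw)
            for q in corpus.questions
        }
        self.aseq: dict[str, PaddedSequence] = {
            a.id: double_level_embed(a, target_len=embed_cfg.answer_len, **kw)
            for a in corpus.answers
        }
        self.query: dict[str, np.ndarray] = {
            qid: attention_query(seq) for qid, seq in self.qseq.items()
        }
        self._tokvec_q: dict[str, np.ndarray] = {}
        self._tokvec_a: dict[str, np.ndarray] = {}
        if embed_cfg.semantic_level == "word":
            for s in corpus.questions:
                self._tokvec_q[s.id] = np.stack(
                    [word_table.lookup(t) for t in s.word_tokens]
                )
            for s in corpus.answers:
                self._tokvec_a[s.id] = np.stack(
                    [word_table.lookup(t) for t in s.word_tokens]
                )
        else:  # combined double-level rows
            for qid, seq in self.qseq.items():
                self._tokvec_q[qid] = seq.valid_rows()
            for aid, seq in self.aseq.items():
                self._tokvec_a[aid] = seq.valid_rows()
        self._sem_cache: dict[tuple[str, str], float] = {}

    @property
    def dimension(self) -> int:
        return self.cfg.dimension

    def semantic(self, qid: str, aid: str) -> float:
        """Cached semantic similarity of a (question, answer) pair; it
        depends on the embedding tables only, never on model parameters."""
        key = (qid, aid)
        val = self._sem_cache.get(key)
        if val is None:
            val = semantic_similarity(self._tokvec_q[qid], self._tokvec_a[aid])
            self._sem_cache[key] = val
        return val


# ---------------------------------------------------------------------------
# batched cosine with backward


def _cosine_fwd(U: np.ndarray, V: np.ndarray):
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    ok = (nu > 0) & (nv > 0)
    denom = np.where(ok, nu * nv, 1.0)
    cos = np.where(ok, (U * V).sum(axis=1) / denom, 0.0)
    return cos, (U, V, nu, nv, cos, ok)


def _cosine_bwd(dcos: np.ndarray, cache):
    U, V, nu, nv, cos, ok = cache
    d = np.where(ok, dcos, 0.0)[:, None]
    nu_ = np.where(nu > 0, nu, 1.0)[:, None]
    nv_ = np.where(nv > 0, nv, 1.0)[:, None]
    dU = d * (V / (nu_ * nv_) - cos[:, None] * U / (nu_ * nu_))
    dV = d * (U / (nu_ * nv_) - cos[:, None] * V / (nv_ * nv_))
    return dU, dV


# ---------------------------------------------------------------------------
# encode-and-pool with backward


def _encode_pooled(model, X, mask, r_q, pooling, train_mode, rng):
    if r_q is not None:
        Xt, att_cache = _attention_forward_batch(X, mask, r_q, model.M_qi)
    else:
        Xt, att_cache = X, None
    R, caches = encode_batch(Xt, mask, model.encoder, train_mode=train_mode, rng=rng)
    pooled, pcache = pool_batch(R, mask, pooling)
    return pooled, (att_cache, caches, pcache)


def _encode_pooled_backward(model, d_pooled, bundle, grads):
    att_cache, caches, pcache = bundle
    dR = pool_backward_batch(d_pooled, pcache)
    dX = encode_backward_batch(dR, caches, model.encoder, grads)
    if att_cache is not None:
        _attention_backward_batch(dX, att_cache, grads["M_qi"])


# ---------------------------------------------------------------------------
# loss on a batch of triples


def triple_batch_loss(
    model: ModelParams,
    feat: Featurizer,
    batch: list[TrainingTriple],
    sim_cfg: SimilarityConfig,
    model_cfg,
    train_mode: bool = False,
    drop_rng: np.random.Generator | None = None,
    compute_grads: bool = True,
):
    """Mean hinge loss over a triple batch and, optionally, its exact
    gradient with respect to every trainable tensor."""
    B = len(batch)
    Xq = np.stack([feat.qseq[t.qid].matrix for t in batch])
    mq = np.stack([feat.qseq[t.qid].mask for t in batch])
    rq = np.stack([feat.query[t.qid] for t in batch])
    Xp = np.stack([feat.aseq[t.pos_aid].matrix for t in batch])
    mp = np.stack([feat.aseq[t.pos_aid].mask for t in batch])
    Xn = np.stack([feat.aseq[t.neg_aid].matrix for t in batch])
    mn = np.stack([feat.aseq[t.neg_aid].mask for t in batch])
    sem_p = np.array([feat.semantic(t.qid, t.pos_aid) for t in batch])
    sem_n = np.array([feat.semantic(t.qid, t.neg_aid) for t in batch])

    pooling = model_cfg.pooling
    rq_q = rq if model_cfg.attend_question else None
    rq_a = rq if model_cfg.attend_answer else None
    q_pooled, q_bundle = _encode_pooled(model, Xq, mq, rq_q, pooling, train_mode, drop_rng)
    p_pooled, p_bundle = _encode_pooled(model, Xp, mp, rq_a, pooling, train_mode, drop_rng)
    n_pooled, n_bundle = _encode_pooled(model, Xn, mn, rq_a, pooling, train_mode, drop_rng)

    cos_p, cp_cache = _cosine_fwd(q_pooled, p_pooled)
    cos_n, cn_cache = _cosine_fwd(q_pooled, n_pooled)
    sim_p = sim_cfg.theta1 * sem_p + sim_cfg.theta2 * cos_p
    sim_n = sim_cfg.theta1 * sem_n + sim_cfg.theta2 * cos_n
    losses = np.maximum(0.0, sim_cfg.margin - sim_p + sim_n)
    loss = float(losses.mean())
    if not compute_grads:
        return loss, losses, None

    grads = zero_grads(model)
    active = (losses > 0).astype(float)
    dcos_p = -sim_cfg.theta2 * active / B
    dcos_n = +sim_cfg.theta2 * active / B
    dq1, dp = _cosine_bwd(dcos_p, cp_cache)
    dq2, dn = _cosine_bwd(dcos_n, cn_cache)
    _encode_pooled_backward(model, dq1 + dq2, q_bundle, grads)
    _encode_pooled_backward(model, dp, p_bundle, grads)
    _encode_pooled_backward(model, dn, n_bundle, grads)
    return loss, losses, grads


# ---------------------------------------------------------------------------
# optimisers


class _Adam:
    def __init__(self, flat, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in flat.items()}
        self.v = {k: np.zeros_like(v) for k, v in flat.items()}
        self.t = 0

    def step(self, flat, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in flat.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, flat, lr):
        self.lr = lr

    def step(self, flat, grads):
        for k, p in flat.items():
            p -= self.lr * grads[k]


# ---------------------------------------------------------------------------
# history and reports


@dataclass(frozen=True)
class HistoryRecord:
    step: int
    loss: float
    train_top1: float | None = None


@dataclass
class TrainingHistory:
    records: list[HistoryRecord] = field(default_factory=list)

    def append(self, rec: HistoryRecord) -> None:
        if self.records and rec.step <= self.records[-1].step:
            raise ValueError("history steps must be strictly increasing")
        self.records.append(rec)

    def to_rows(self) -> list[tuple]:
        return [(r.step, r.loss, r.train_top1) for r in self.records]


@dataclass
class EvalReport:
    top1: float
    top2: float
    top3: float
    precision: float
    recall: float
    f1: float
    ranked: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        if not (0 <= self.top1 <= self.top2 <= self.top3 <= 1):
            raise ValueError("top-k accuracies must be nested in [0, 1]")


# ---------------------------------------------------------------------------
# scoring


class Scorer:
    """Ranks answer pools by the joint similarity.

    With a model, the text term is the cosine of the pooled encoder
    representations (answers gated by their question's attention query);
    without one, it falls back to the cosine of mean token embeddings —
    the untrained mode.
    """

    def __init__(
        self,
        feat: Featurizer,
        sim_cfg: SimilarityConfig,
        model: ModelParams | None = None,
        model_cfg=None,
    ):
        self.feat = feat
        self.sim_cfg = sim_cfg
        self.model = model
        self.model_cfg = model_cfg
        if model is not None and model_cfg is None:
            raise ValueError("a model requires its model configuration")

    def _text_cosines(self, pools: list[AnswerPool]) -> dict[tuple[str, str], float]:
        feat = self.feat
        pairs = [(p.qid, aid) for p in pools for aid in p.candidates]
        qids = [p.qid for p in pools]
        if self.model is None:
            qrep = {q: feat.qseq[q].valid_rows().mean(axis=0) for q in set(qids)}
            arep = {}
            out = {}
            for qid, aid in pairs:
                if aid not in arep:
                    arep[aid] = feat.aseq[aid].valid_rows().mean(axis=0)
                cos, _ = _cosine_fwd(qrep[qid][None], arep[aid][None])
                out[(qid, aid)] = float(cos[0])
            return out
        mc = self.model_cfg
        # questions, one encode per distinct qid
        uq = sorted(set(qids))
        Xq = np.stack([feat.qseq[q].matrix for q in uq])
        mq = np.stack([feat.qseq[q].mask for q in uq])
        rq = np.stack([feat.query[q] for q in uq])
        q_pooled, _ = _encode_pooled(
            self.model, Xq, mq, rq if mc.attend_question else None, mc.pooling, False, None
        )
        q_repr = {q: q_pooled[i] for i, q in enumerate(uq)}
        # answers, one encode per (question, answer) pair since the gate
        # is question-conditioned
        Xa = np.stack([feat.aseq[aid].matrix for _, aid in pairs])
        ma = np.stack([feat.aseq[aid].mask for _, aid in pairs])
        ra = np.stack([feat.query[qid] for qid, _ in pairs])
        a_pooled, _ = _encode_pooled(
            self.model, Xa, ma, ra if mc.attend_answer else None, mc.pooling, False, None
        )
        U = np.stack([q_repr[qid] for qid, _ in pairs])
        cos, _ = _cosine_fwd(U, a_pooled)
        return {pair: float(c) for pair, c in zip(pairs, cos)}

    def score_pools(
        self, pools: list[AnswerPool]
    ) -> dict[str, list[tuple[str, float]]]:
        text = self._text_cosines(pools)
        th1, th2 = self.sim_cfg.theta1, self.sim_cfg.theta2
        out = {}
        for p in pools:
            scored = [
                (aid, th1 * self.feat.semantic(p.qid, aid) + th2 * text[(p.qid, aid)])
                for aid in p.candidates
            ]
            scored.sort(key=lambda x: (-x[1], x[0]))
            out[p.qid] = scored
        return out

    def score_pool(self, pool: AnswerPool) -> list[tuple[str, float]]:
        return self.score_pools([pool])[pool.qid]


def score_pool(
    model: ModelParams | None,
    sim_cfg: SimilarityConfig,
    pool: AnswerPool,
    feat: Featurizer,
    model_cfg=None,
) -> list[tuple[str, float]]:
    """Candidates of one pool sorted by joint similarity, descending;
    ties broken by candidate id ascending."""
    for aid in pool.candidates:
        if aid not in feat.aseq:
            raise KeyError(f"candidate {aid!r} missing from corpus")
    return Scorer(feat, sim_cfg, model, model_cfg).score_pool(pool)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(pools: list[AnswerPool], scorer) -> EvalReport:
    """Top-k accuracy for k in {1,2,3} plus precision/recall/F1 of the
    top-1 retrieval over a pool collection.

    `scorer` is a Scorer or any callable mapping a pool to its ranked
    (aid, score) list.
    """
    if not pools:
        raise ValueError("evaluate requires at least one pool")
    if hasattr(scorer, "score_pools"):
        ranked = scorer.score_pools(pools)
    else:
        ranked = {p.qid: scorer(p) for p in pools}
    hits = {k: 0 for k in (1, 2, 3)}
    top1_hits = 0
    total_gt = 0
    for p in pools:
        order = [aid for aid, _ in ranked[p.qid]]
        total_gt += len(p.ground_truth)
        for k in (1, 2, 3):
            if set(order[:k]) & p.ground_truth:
                hits[k] += 1
        if order and order[0] in p.ground_truth:
            top1_hits += 1
    n = len(pools)
    precision = top1_hits / n
    recall = top1_hits / total_gt
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalReport(
        top1=hits[1] / n,
        top2=hits[2] / n,
        top3=hits[3] / n,
        precision=precision,
        recall=recall,
        f1=f1,
        ranked=ranked,
    )


def steps_to_threshold(history: TrainingHistory, threshold: float = 0.5) -> int | None:
    """First step index whose recorded train-pool top-1 accuracy reaches
    the threshold; None if it never does."""
    if not history.records:
        raise ValueError("empty training history")
    for rec in history.records:
        if rec.train_top1 is not None and rec.train_top1 >= threshold:
            return rec.step
    return None


# ---------------------------------------------------------------------------
# training loop


def train(
    corpus: QACorpus,
    triples: list[TrainingTriple],
    word_table: EmbeddingTable,
    char_table: EmbeddingTable,
    cfg: Config,
    eval_pools: list[AnswerPool] | None = None,
    model: ModelParams | None = None,
    feat: Featurizer | None = None,
) -> tuple[ModelParams, TrainingHistory]:
    """Minimise the mean hinge loss over the triples.

    Fully deterministic under the configured seeds: data order, dropout
    and initialisation all derive from them.  When `eval_pools` is given,
    train-pool top-1 accuracy is recorded every `eval_every` steps
    (default: once per epoch).
    """
    if feat is None:
        feat = Featurizer(corpus, word_table, char_table, cfg.embedding)
    if model is None:
        model = init_model_params(
            cfg.embedding.dimension,
            cfg.model.hidden,
            cfg.model.n_layers,
            cfg.model.dropout,
            cfg.model.seed,
            cfg.model.init_scale,
        )
    else:
        model = copy.deepcopy(model)  # never mutate the caller's parameters
    flat = flatten_params(model)
    opt = (
        _Adam(flat, cfg.train.learning_rate)
        if cfg.train.optimizer == "adam"
        else _SGD(flat, cfg.train.learning_rate)
    )
    order_rng = np.random.default_rng([cfg.train.seed, 17])
    drop_rng = np.random.default_rng([cfg.train.seed, 23])
    B = cfg.train.batch_size
    steps_per_epoch = max(1, (len(triples) + B - 1) // B)
    eval_every = cfg.train.eval_every or steps_per_epoch
    scorer = (
        Scorer(feat, cfg.similarity, model, cfg.model) if eval_pools else None
    )
    history = TrainingHistory()
    step = 0
    for _epoch in range(cfg.train.epochs):
        order = order_rng.permutation(len(triples))
        for lo in range(0, len(triples), B):
            batch = [triples[i] for i in order[lo : lo + B]]
            loss, _, grads = triple_batch_loss(
                model,
                feat,
                batch,
                cfg.similarity,
                cfg.model,
                train_mode=True,
                drop_rng=drop_rng,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss!r} at step {step + 1};"
                    " lower the learning rate"
                )
            opt.step(flat, grads)
            step += 1
            top1 = None
            if scorer is not None and step % eval_every == 0:
                top1 = evaluate(eval_pools, scorer).top1
            history.append(HistoryRecord(step, loss, top1))
    return model, history
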