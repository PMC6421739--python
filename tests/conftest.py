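import numpy as np
import pytest

from qarank.config import EmbedConfig, ModelConfig
from qarank.corpus import QACorpus, Sentence
from qarank.embedding import EmbeddingTable
from qarank.train_eval import Featurizer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_corpus(rng):
    """Two questions, four answers, one positive each; random tokens
    over a six-word / six-character inventory."""
    words = [f"w{i}" for i in range(6)]
    chars = [f"c{i}" for i in range(6)]

    def sent(sid, n):
        return Sentence(
            sid,
            tuple(rng.choice(words, n)),
            tuple(rng.choice(chars, n)),
        )

    questions = [sent("q0", 3), sent("q1", 2)]
    answers = [sent(f"a{i}", 4) for i in range(4)]
    return QACorpus(questions, answers, {("q0", "a0"), ("q1", "a1")})


@pytest.fixture
def tiny_tables(rng):
    d = 3
    wt = EmbeddingTable(d, {f"w{i}": rng.normal(size=d) for i in range(6)})
    ct = EmbeddingTable(d, {f"c{i}": rng.normal(size=d) for i in range(6)})
    return wt, ct


@pytest.fixture
def tiny_featurizer(tiny_corpus, tiny_tables):
    wt, ct = tiny_tables
    ecfg = EmbedConfig(dimension=3, question_len=4, answer_len=4)
    return Featurizer(tiny_corpus, wt, ct, ecfg)


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(hidden=2, n_layers=2, dropout=0.5, seed=1)
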