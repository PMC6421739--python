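"""Joint question-answer similarity and the margin ranking objective.

The score assigned to a candidate answer combines two terms:

* a *semantic* max-alignment similarity computed directly on the static
  token embeddings of the two sentences: every token of one sentence is
  matched with its best cosine partner in the other, both directional sums
  are added and normalised by the total token count,

      Sim_semantic(Q, A) = (sum_i max_j cos(q_i, a_j)
                            + sum_j max_i cos(q_i, a_j)) / (m + n)

* a *text* similarity: the cosine of the two pooled encoder
  representations.

The joint score is the convex combination

      Sim(q, a) = theta1 * Sim_semantic + (1 - theta1) * Sim_text

and training minimises the hinge (margin) loss

      L = max(0, M - Sim(q, a+) + Sim(q, a-))

over (question, correct answer, wrong answer) triples.  Because the
semantic term is a function of the fixed embedding tables only, gradients
flow exclusively through the text term; the semantic term shifts each
triple's effective margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityConfig",
    "cosine",
    "semantic_similarity",
    "joint_similarity",
    "hinge_loss",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Weights of the joint similarity and the ranking margin.

    theta1 weighs the semantic (max-alignment) term; the text term gets
    1 - theta1.  margin is the minimum score gap the hinge objective
    demands between a correct and a wrong answer.
    """

    theta1: float = 0.6
    margin: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta1 <= 1.0:
            raise ValueError(f"theta1 must lie in [0, 1], got {self.theta1}")
        if not self.margin > 0:
            raise ValueError(f"margin must be positive, got {self.margin}")

    @property
    def theta2(self) -> float:
        return 1.0 - self.theta1


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two vectors; 0 if either has zero norm.

    Zero vectors arise from the out-of-vocabulary embedding policy; they
    contribute a neutral 0 rather than raising.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _cosine_matrix(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    """All-pairs cosine matrix, rows of zero norm contributing 0."""
    qn = np.linalg.norm(Q, axis=1, keepdims=True)
    an = np.linalg.norm(A, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Qh = np.where(qn > 0, Q / np.where(qn == 0, 1.0, qn), 0.0)
        Ah = np.where(an > 0, A / np.where(an == 0, 1.0, an), 0.0)
    return Qh @ Ah.T


def semantic_similarity(Q: np.ndarray, A: np.ndarray) -> float:
    """Max-alignment similarity between two token-vector sets.

    Q is an (m, d) array of the question's token vectors, A an (n, d)
    array of the answer's.  Each token is aligned with its best cosine
    match in the other sentence; the two directional sums are normalised
    by m + n.  The result lies in [-1, 1], is symmetric in its arguments,
    and equals 1 exactly when every token of each sentence has a
    perfect-cosine partner in the other.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if Q.shape[0] == 0 or A.shape[0] == 0:
        raise ValueError("semantic_similarity requires non-empty token sets")
    if Q.shape[1] != A.shape[1]:
        raise ValueError(
            f"token dimension mismatch: {Q.shape[1]} vs {A.shape[1]}"
        )
    C = _cosine_matrix(Q, A)
    m, n = C.shape
    return float((C.max(axis=1).sum() + C.max(axis=0).sum()) / (m + n))


def joint_similarity(
    q_repr: np.ndarray,
    a_repr: np.ndarray,
    Q: np.ndarray,
    A: np.ndarray,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> float:
    """theta1-weighted combination of semantic and text similarity.

    q_repr / a_repr are the pooled encoder representations of the two
    sentences; Q / A the static token-embedding sets used by the
    semantic term.
    """
    sem = semantic_similarity(Q, A)
    text = cosine(q_repr, a_repr)
    return cfg.theta1 * sem + cfg.theta2 * text


def hinge_loss(sim_pos: float, sim_neg: float, margin: float = 0.1) -> float:
    """max(0, margin - sim_pos + sim_neg); zero once the positive
    outranks the negative by at least the margin."""
    if not margin > 0:
        raise ValueError(f"margin must be positive, got {margin}")
    return max(0.0, margin - sim_pos + sim_neg)
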