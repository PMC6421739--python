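"""Inner-attention gated, stacked Bi-LSTM sentence encoder.

The encoder turns a padded embedded sentence into a fixed-size vector in
three stages:

1. *Inner attention*: each input embedding x_t is scaled by a sigmoid
   gate computed from a question vector r_q before any recurrence,

       alpha_t = sigmoid(r_q^T M_qi x_t),     x~_t = alpha_t * x_t,

   which counteracts the tendency of attention applied after a recurrent
   network to overweight sentence-final positions.  r_q is data-derived
   (the mean of the question's valid embedding rows); M_qi is the
   trainable attention matrix.

2. *Stacked Bi-LSTM*: standard LSTM cells run left-to-right and
   right-to-left over the valid positions; per position the two hidden
   states are concatenated, r_t = [h->_t || h<-_t].  Dropout is applied
   between stacked layers in training mode only, never on recurrent
   connections.  Question and answer encoders share all parameters.

3. *Pooling*: coordinate-wise max (default) or mean over valid
   positions yields the sentence representation.

Everything is implemented in NumPy with an explicit backward pass
(backpropagation through time), so gradients of the ranking objective
are exact and checkable against finite differences.  The batched
functions carry a cache from forward to backward; the single-sequence
functions mirror the public per-operation contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .embedding import PaddedSequence

__all__ = [
    "GATES",
    "AttentionParams",
    "LSTMParams",
    "EncoderParams",
    "ModelParams",
    "init_model_params",
    "attention_query",
    "attention_weights",
    "apply_inner_attention",
    "lstm_step",
    "encode",
    "max_pool",
    "mean_pool",
    "flatten_params",
    "set_flat_params",
    "save_checkpoint",
    "load_checkpoint",
]

GATES = ("i", "f", "o", "c")  # input, forget, output, candidate


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AttentionParams:
    """Per-call attention bundle: the question vector r_q (data-derived,
    not trained) and the trainable projection M_qi, with
    alpha_t = sigmoid(r_q^T M_qi x_t)."""

    r_q: np.ndarray  # (d_r,)
    M_qi: np.ndarray  # (d_r, d_in)

    def __post_init__(self) -> None:
        if self.M_qi.ndim != 2 or self.r_q.shape != (self.M_qi.shape[0],):
            raise ValueError(
                f"attention shapes not conformable: r_q {self.r_q.shape},"
                f" M_qi {self.M_qi.shape}"
            )


@dataclass
class LSTMParams:
    """One direction's cell parameters: per gate an input matrix W
    (D x H), recurrent matrix U (H x H) and bias b (H)."""

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        D, H = self.W["i"].shape
        for g in GATES:
            if self.W[g].shape != (D, H) or self.U[g].shape != (H, H) or self.b[
                g
            ].shape != (H,):
                raise ValueError(f"inconsistent LSTM parameter shapes at gate {g!r}")

    @property
    def input_dim(self) -> int:
        return self.W["i"].shape[0]

    @property
    def hidden(self) -> int:
        return self.W["i"].shape[1]


@dataclass
class EncoderParams:
    """Stacked bidirectional encoder: per layer a (forward, backward)
    LSTMParams pair; in training mode dropout acts on each layer's
    output (never on recurrent connections)."""

    layers: list[tuple[LSTMParams, LSTMParams]]
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("encoder needs at least one layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        for ell in range(1, len(self.layers)):
            need = 2 * self.layers[ell - 1][0].hidden
            if self.layers[ell][0].input_dim != need:
                raise ValueError(
                    f"layer {ell} input dim {self.layers[ell][0].input_dim}"
                    f" != 2H of layer {ell - 1} ({need})"
                )

    @property
    def hidden(self) -> int:
        return self.layers[-1][0].hidden

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class ModelParams:
    """All trainable quantities: the attention projection and the
    per-direction, per-layer LSTM parameters (shared between the
    question and answer encoders)."""

    M_qi: np.ndarray
    encoder: EncoderParams


def _init_lstm(rng: np.random.Generator, d: int, h: int, scale: float) -> LSTMParams:
    def orth(n: int) -> np.ndarray:
        q, r = np.linalg.qr(rng.standard_normal((n, n)))
        return q * np.sign(np.diag(r))

    W = {g: rng.uniform(-scale, scale, (d, h)) for g in GATES}
    U = {g: orth(h) for g in GATES}
    b = {g: np.zeros(h) for g in GATES}
    b["f"] = np.ones(h)  # forget-gate bias 1: remember by default
    return LSTMParams(W, U, b)


def init_model_params(
    embed_dim: int,
    hidden: int = 200,
    n_layers: int = 2,
    dropout: float = 0.5,
    seed: int = 0,
    init_scale: float = 0.08,
) -> ModelParams:
    """Orthogonal recurrent matrices, small-uniform input matrices,
    forget bias 1, deterministic under seed."""
    rng = np.random.default_rng([seed, 11])
    layers = []
    d = embed_dim
    for _ in range(n_layers):
        layers.append(
            (_init_lstm(rng, d, hidden, init_scale), _init_lstm(rng, d, hidden, init_scale))
        )
        d = 2 * hidden
    M_qi = rng.uniform(-init_scale, init_scale, (embed_dim, embed_dim))
    return ModelParams(M_qi, EncoderParams(layers, dropout))


# ---------------------------------------------------------------------------
# attention


def attention_query(seq: PaddedSequence) -> np.ndarray:
    """The question vector r_q: mean of the valid embedding rows."""
    if seq.n_valid == 0:
        raise ValueError("cannot derive an attention query from an all-padded input")
    return seq.valid_rows().mean(axis=0)


def attention_weights(seq: PaddedSequence, params: AttentionParams) -> np.ndarray:
    """alpha_t = sigmoid(r_q^T M_qi x_t) at valid positions, 0 at padding.
    Values at valid positions lie strictly in (0, 1)."""
    if params.M_qi.shape[1] != seq.matrix.shape[1]:
        raise ValueError(
            f"M_qi maps dimension {params.M_qi.shape[1]},"
            f" input rows have {seq.matrix.shape[1]}"
        )
    s = seq.matrix @ params.M_qi.T @ params.r_q
    return np.where(seq.mask, _sigmoid(s), 0.0)


def apply_inner_attention(
    seq: PaddedSequence, params: AttentionParams
) -> PaddedSequence:
    """Scale each row by its attention gate; mask unchanged."""
    alpha = attention_weights(seq, params)
    return PaddedSequence(alpha[:, None] * seq.matrix, seq.mask.copy())


def _attention_forward_batch(X, mask, r_q, M_qi):
    """X (B,T,d), mask (B,T) bool, r_q (B,d).  Returns gated X and cache."""
    s = np.einsum("btd,ed,be->bt", X, M_qi, r_q)
    sig = _sigmoid(s)
    alpha = np.where(mask, sig, 0.0)
    return alpha[:, :, None] * X, (X, mask, r_q, sig)


def _attention_backward_batch(d_out, cache, dM_qi):
    X, mask, r_q, sig = cache
    dalpha = np.einsum("btd,btd->bt", d_out, X)
    ds = np.where(mask, dalpha * sig * (1.0 - sig), 0.0)
    dM_qi += np.einsum("bt,be,btd->ed", ds, r_q, X)


# ---------------------------------------------------------------------------
# LSTM cell and directional runs


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update:

        i = sig(W_i x + U_i h + b_i)     f = sig(W_f x + U_f h + b_f)
        o = sig(W_o x + U_o h + b_o)     g = tanh(W_c x + U_c h + b_c)
        c_t = i * g + f * c_prev         h_t = o * tanh(c_t)
    """
    if x_t.shape != (p.input_dim,) or h_prev.shape != (p.hidden,) or c_prev.shape != (
        p.hidden,
    ):
        raise ValueError(
            f"lstm_step shape mismatch: x {x_t.shape}, h {h_prev.shape},"
            f" c {c_prev.shape} vs (D={p.input_dim}, H={p.hidden})"
        )
    a = {g: x_t @ p.W[g] + h_prev @ p.U[g] + p.b[g] for g in GATES}
    i = _sigmoid(a["i"])
    f = _sigmoid(a["f"])
    o = _sigmoid(a["o"])
    g = np.tanh(a["c"])
    c_t = i * g + f * c_prev
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def _lstm_dir_forward(Z, mask, p: LSTMParams, reverse: bool):
    B, T, _ = Z.shape
    H = p.hidden
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.zeros((B, T, H))
    steps = range(T - 1, -1, -1) if reverse else range(T)
    cache = []
    for t in steps:
        m = mask[:, t].astype(float)[:, None]
        x = Z[:, t]
        a = {g: x @ p.W[g] + h @ p.U[g] + p.b[g] for g in GATES}
        ig = _sigmoid(a["i"])
        fg = _sigmoid(a["f"])
        og = _sigmoid(a["o"])
        gg = np.tanh(a["c"])
        c_new = ig * gg + fg * c
        tc = np.tanh(c_new)
        h_new = og * tc
        cache.append((t, x, h, c, ig, fg, og, gg, tc, m))
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        out[:, t] = m * h_new
    return out, cache


def _lstm_dir_backward(dOut, cache, p: LSTMParams, grads, prefix):
    B, T, _ = dOut.shape
    H = p.hidden
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    dZ = np.zeros((B, T, p.input_dim))
    for t, x, h_prev, c_prev, ig, fg, og, gg, tc, m in reversed(cache):
        dh_new = m * (dOut[:, t] + dh)
        dh = (1.0 - m) * dh
        dc_new = m * dc
        dc = (1.0 - m) * dc
        do = dh_new * tc
        dc_new = dc_new + dh_new * og * (1.0 - tc * tc)
        di = dc_new * gg
        dg = dc_new * ig
        df = dc_new * c_prev
        dc = dc + dc_new * fg
        da = {
            "i": di * ig * (1.0 - ig),
            "f": df * fg * (1.0 - fg),
            "o": do * og * (1.0 - og),
            "c": dg * (1.0 - gg * gg),
        }
        for g in GATES:
            grads[f"{prefix}.W_{g}"] += x.T @ da[g]
            grads[f"{prefix}.U_{g}"] += h_prev.T @ da[g]
            grads[f"{prefix}.b_{g}"] += da[g].sum(axis=0)
            dZ[:, t] += da[g] @ p.W[g].T
            dh += da[g] @ p.U[g].T
    return dZ


# ---------------------------------------------------------------------------
# stacked bidirectional encoder


def encode_batch(
    X: np.ndarray,
    mask: np.ndarray,
    enc: EncoderParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Batched stacked Bi-LSTM.  Returns (R (B,T,2H), cache); padded
    positions of R are zero.  In training mode an inverted-dropout mask
    drawn from `rng` is applied to every layer's output r_t (never to the
    recurrent connections)."""
    if train_mode and enc.dropout > 0 and rng is None:
        raise ValueError("train_mode dropout requires an rng")
    Z = X
    caches = []
    for ell, (pf, pb) in enumerate(enc.layers):
        out_f, cf = _lstm_dir_forward(Z, mask, pf, reverse=False)
        out_b, cb = _lstm_dir_forward(Z, mask, pb, reverse=True)
        R = np.concatenate([out_f, out_b], axis=2)
        dm = None
        if train_mode and enc.dropout > 0:
            keep = 1.0 - enc.dropout
            dm = (rng.random(R.shape) < keep) / keep
            R = R * dm
        caches.append((cf, cb, dm))
        Z = R
    return Z, caches


def encode_backward_batch(dR, caches, enc: EncoderParams, grads, prefix="enc"):
    """Backpropagate through the stack; returns gradient w.r.t. the
    (post-attention) input X."""
    for ell in range(enc.n_layers - 1, -1, -1):
        cf, cb, dm = caches[ell]
        if dm is not None:
            dR = dR * dm
        pf, pb = enc.layers[ell]
        H = pf.hidden
        dZf = _lstm_dir_backward(dR[:, :, :H], cf, pf, grads, f"{prefix}.l{ell}.fwd")
        dZb = _lstm_dir_backward(dR[:, :, H:], cb, pb, grads, f"{prefix}.l{ell}.bwd")
        dR = dZf + dZb
    return dR


def encode(
    seq: PaddedSequence,
    enc: EncoderParams,
    train_mode: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Encode a single padded sequence to its T x 2H representation."""
    rng = np.random.default_rng([seed, 13]) if train_mode else None
    R, _ = encode_batch(
        seq.matrix[None], seq.mask[None], enc, train_mode=train_mode, rng=rng
    )
    return R[0]


# ---------------------------------------------------------------------------
# pooling


def max_pool(encoded: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Coordinate-wise maximum over valid positions only."""
    if not mask.any():
        raise ValueError("max_pool over an all-padded sequence")
    return encoded[mask].max(axis=0)


def mean_pool(encoded: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean over valid positions only."""
    if not mask.any():
        raise ValueError("mean_pool over an all-padded sequence")
    return encoded[mask].mean(axis=0)


def pool_batch(R: np.ndarray, mask: np.ndarray, pooling: str = "max"):
    """Masked pooling with a cache for the backward pass."""
    if pooling == "max":
        neg = np.where(mask[:, :, None], R, -np.inf)
        arg = neg.argmax(axis=1)  # (B, 2H)
        pooled = np.take_along_axis(R, arg[:, None, :], axis=1)[:, 0, :]
        return pooled, ("max", arg, R.shape)
    if pooling == "mean":
        counts = mask.sum(axis=1, keepdims=True).astype(float)
        pooled = (R * mask[:, :, None]).sum(axis=1) / counts
        return pooled, ("mean", mask, counts, R.shape)
    raise ValueError(f"unknown pooling {pooling!r}")


def pool_backward_batch(d_pooled: np.ndarray, cache):
    kind = cache[0]
    if kind == "max":
        _, arg, shape = cache
        dR = np.zeros(shape)
        np.put_along_axis(dR, arg[:, None, :], d_pooled[:, None, :], axis=1)
        return dR
    _, mask, counts, shape = cache
    dR = np.zeros(shape)
    dR += (d_pooled / counts)[:, None, :]
    return dR * mask[:, :, None]


# ---------------------------------------------------------------------------
# parameter flattening and checkpoints

_CKPT_VERSION = 1


def flatten_params(model: ModelParams) -> dict[str, np.ndarray]:
    """Stable name -> array view of every trainable tensor."""
    flat: dict[str, np.ndarray] = {"M_qi": model.M_qi}
    for ell, (pf, pb) in enumerate(model.encoder.layers):
        for name, p in (("fwd", pf), ("bwd", pb)):
            for g in GATES:
                flat[f"enc.l{ell}.{name}.W_{g}"] = p.W[g]
                flat[f"enc.l{ell}.{name}.U_{g}"] = p.U[g]
                flat[f"enc.l{ell}.{name}.b_{g}"] = p.b[g]
    return flat


def zero_grads(model: ModelParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in flatten_params(model).items()}


def set_flat_params(model: ModelParams, flat: dict[str, np.ndarray]) -> None:
    """Write values back into the model's tensors in place."""
    model.M_qi[...] = flat["M_qi"]
    for ell, (pf, pb) in enumerate(model.encoder.layers):
        for name, p in (("fwd", pf), ("bwd", pb)):
            for g in GATES:
                p.W[g][...] = flat[f"enc.l{ell}.{name}.W_{g}"]
                p.U[g][...] = flat[f"enc.l{ell}.{name}.U_{g}"]
                p.b[g][...] = flat[f"enc.l{ell}.{name}.b_{g}"]


def save_checkpoint(path, model: ModelParams, config: dict) -> None:
    """Single-archive checkpoint: every parameter tensor plus the
    originating configuration (JSON) and a format version."""
    flat = flatten_params(model)
    meta = {
        "version": _CKPT_VERSION,
        "n_layers": model.encoder.n_layers,
        "dropout": model.encoder.dropout,
        "config": config,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ), **flat)


def load_checkpoint(path) -> tuple[ModelParams, dict]:
    """Inverse of save_checkpoint; returns (model, config)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta.get("version") != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        flat = {k: data[k] for k in data.files if k != "__meta__"}
    layers = []
    for ell in range(meta["n_layers"]):
        pair = []
        for name in ("fwd", "bwd"):
            pair.append(
                LSTMParams(
                    {g: flat[f"enc.l{ell}.{name}.W_{g}"] for g in GATES},
                    {g: flat[f"enc.l{ell}.{name}.U_{g}"] for g in GATES},
                    {g: flat[f"enc.l{ell}.{name}.b_{g}"] for g in GATES},
                )
            )
        layers.append((pair[0], pair[1]))
    model = ModelParams(flat["M_qi"], EncoderParams(layers, meta["dropout"]))
    return model, meta["config"]
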