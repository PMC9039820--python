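"""Minimal NumPy Transformer encoder–decoder with explicit backpropagation.

Forward and backward passes are written out layer by layer (pre-layer-norm
variant), which keeps the implementation dependency-free, deterministic
under a single seed, and small enough to gradient-check against finite
differences.  Shapes follow the (batch, time, width) convention; attention
masks are additive (0 for valid positions, a large negative number for
masked ones).  Every stochastic element — initialization and dropout —
draws from the one ``Generator`` owned by the model.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e9


class Tensor:
    """A parameter array paired with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.tensors())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.tensors())
        return out


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)).astype(dtype))
        self.b = Tensor(np.zeros(d_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.data.shape
        self.W.grad += x.reshape(-1, d_in).T @ dy.reshape(-1, d_out)
        self.b.grad += dy.reshape(-1, d_out).sum(axis=0)
        return dy @ self.W.data.T


class Embedding(Module):
    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator, dtype=np.float32):
        self.table = Tensor((rng.standard_normal((n_vocab, d_model)) * d_model**-0.5).astype(dtype))
        self._ids: np.ndarray | None = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.table.data[ids]

    def backward(self, dy: np.ndarray) -> None:
        d = self.table.data.shape[1]
        np.add.at(self.table.grad, self._ids.reshape(-1), dy.reshape(-1, d))


class LayerNorm(Module):
    def __init__(self, d_model: int, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d_model, dtype=dtype))
        self.beta = Tensor(np.zeros(d_model, dtype=dtype))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += dy.reshape(-1, xhat.shape[-1]).sum(axis=0)
        dxhat = dy * self.gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


class Dropout(Module):
    """Inverted dropout; the mask comes from the model-owned generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng, dtype)
        self.wk = Dense(d_model, d_model, rng, dtype)
        self.wv = Dense(d_model, d_model, rng, dtype)
        self.wo = Dense(d_model, d_model, rng, dtype)

    def _split(self, x: np.ndarray) -> np.ndarray:  # (B,T,D) -> (B,h,T,dk)
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:  # (B,h,T,dk) -> (B,T,D)
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, q_in: np.ndarray, k_in: np.ndarray, v_in: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
        Q = self._split(self.wq.forward(q_in))
        K = self._split(self.wk.forward(k_in))
        V = self._split(self.wv.forward(v_in))
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        if mask is not None:
            scores = scores + mask
        P = softmax(scores, axis=-1)
        self._Q, self._K, self._V, self._P = Q, K, V, P
        out = self._merge(P @ V)
        return self.wo.forward(out)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns gradients w.r.t. (q_in, k_in, v_in)."""
        Q, K, V, P = self._Q, self._K, self._V, self._P
        d_merged = self.wo.backward(dy)
        dO = self._split(d_merged)  # (B,h,Tq,dk)
        dP = dO @ V.transpose(0, 1, 3, 2)
        dV = P.transpose(0, 1, 3, 2) @ dO
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.d_k)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dq_in = self.wq.backward(self._merge(dQ))
        dk_in = self.wk.backward(self._merge(dK))
        dv_in = self.wv.backward(self._merge(dV))
        return dq_in, dk_in, dv_in


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator, dtype=np.float32):
        self.fc1 = Dense(d_model, d_ff, rng, dtype)
        self.fc2 = Dense(d_ff, d_model, rng, dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.fc1.forward(x)
        self._relu_mask = h > 0
        return self.fc2.forward(h * self._relu_mask)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dy) * self._relu_mask
        return self.fc1.backward(dh)


class EncoderLayer(Module):
    def __init__(self, d_model, n_heads, d_ff, dropout, rng, dtype=np.float32):
        self.ln1 = LayerNorm(d_model, dtype)
        self.attn = MultiHeadAttention(d_model, n_heads, rng, dtype)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(d_model, dtype)
        self.ffn = FeedForward(d_model, d_ff, rng, dtype)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x, mask, train):
        h = self.ln1.forward(x)
        x = x + self.drop1.forward(self.attn.forward(h, h, h, mask), train)
        h = self.ln2.forward(x)
        return x + self.drop2.forward(self.ffn.forward(h), train)

    def backward(self, dy):
        dh = self.ln2.backward(self.ffn.backward(self.drop2.backward(dy)))
        dx = dy + dh
        dq, dk, dv = self.attn.backward(self.drop1.backward(dx))
        return dx + self.ln1.backward(dq + dk + dv)


class DecoderLayer(Module):
    def __init__(self, d_model, n_heads, d_ff, dropout, rng, dtype=np.float32):
        self.ln1 = LayerNorm(d_model, dtype)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng, dtype)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(d_model, dtype)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng, dtype)
        self.drop2 = Dropout(dropout, rng)
        self.ln3 = LayerNorm(d_model, dtype)
        self.ffn = FeedForward(d_model, d_ff, rng, dtype)
        self.drop3 = Dropout(dropout, rng)

    def forward(self, x, enc_out, self_mask, cross_mask, train):
        h = self.ln1.forward(x)
        x = x + self.drop1.forward(self.self_attn.forward(h, h, h, self_mask), train)
        h = self.ln2.forward(x)
        x = x + self.drop2.forward(self.cross_attn.forward(h, enc_out, enc_out, cross_mask), train)
        h = self.ln3.forward(x)
        return x + self.drop3.forward(self.ffn.forward(h), train)

    def backward(self, dy):
        """Returns (dx, d_enc_out)."""
        dh = self.ln3.backward(self.ffn.backward(self.drop3.backward(dy)))
        dx = dy + dh
        dq, dk, dv = self.cross_attn.backward(self.drop2.backward(dx))
        d_enc = dk + dv
        dx = dx + self.ln2.backward(dq)
        dq, dk, dv = self.self_attn.backward(self.drop1.backward(dx))
        dx = dx + self.ln1.backward(dq + dk + dv)
        return dx, d_enc


def sinusoidal_positions(max_len: int, d_model: int, dtype=np.float32) -> np.ndarray:
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(dtype)


class Transformer(Module):
    """Encoder–decoder with token embeddings, sinusoidal positions, tied masks.

    ``pad_id`` is shared by source and target streams; padded positions are
    excluded from attention and from the loss.
    """

    def __init__(
        self,
        src_vocab: int,
        tgt_vocab: int,
        d_model: int = 64,
        n_heads: int = 4,
        d_ff: int = 128,
        n_enc_layers: int = 2,
        n_dec_layers: int = 2,
        dropout: float = 0.1,
        max_len: int = 256,
        pad_id: int = 0,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.rng = np.random.default_rng(seed)
        self.pad_id = pad_id
        self.d_model = d_model
        self.dtype = dtype
        self.src_emb = Embedding(src_vocab, d_model, self.rng, dtype)
        self.tgt_emb = Embedding(tgt_vocab, d_model, self.rng, dtype)
        self.pos = sinusoidal_positions(max_len, d_model, dtype)
        self.emb_drop_src = Dropout(dropout, self.rng)
        self.emb_drop_tgt = Dropout(dropout, self.rng)
        self.enc_layers = [
            EncoderLayer(d_model, n_heads, d_ff, dropout, self.rng, dtype)
            for _ in range(n_enc_layers)
        ]
        self.dec_layers = [
            DecoderLayer(d_model, n_heads, d_ff, dropout, self.rng, dtype)
            for _ in range(n_dec_layers)
        ]
        self.enc_ln = LayerNorm(d_model, dtype)
        self.dec_ln = LayerNorm(d_model, dtype)
        self.out_proj = Dense(d_model, tgt_vocab, self.rng, dtype)

    # -- masks --------------------------------------------------------------

    def _pad_mask(self, ids: np.ndarray) -> np.ndarray:
        # (B,1,1,T) additive mask over keys
        m = np.zeros((ids.shape[0], 1, 1, ids.shape[1]), dtype=self.dtype)
        m[:, 0, 0, :][ids == self.pad_id] = NEG_INF
        return m

    @staticmethod
    def _causal_mask(T: int, dtype) -> np.ndarray:
        m = np.triu(np.full((T, T), NEG_INF, dtype=dtype), k=1)
        return m[None, None, :, :]

    # -- forward ------------------------------------------------------------

    def encode(self, src_ids: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        mask = self._pad_mask(src_ids)
        x = self.src_emb.forward(src_ids) * np.sqrt(self.d_model) + self.pos[: src_ids.shape[1]]
        x = self.emb_drop_src.forward(x.astype(self.dtype), train)
        for layer in self.enc_layers:
            x = layer.forward(x, mask, train)
        return self.enc_ln.forward(x), mask

    def decode(
        self, enc_out: np.ndarray, enc_mask: np.ndarray, tgt_in: np.ndarray, train: bool = False
    ) -> np.ndarray:
        T = tgt_in.shape[1]
        self_mask = self._causal_mask(T, self.dtype) + self._pad_mask(tgt_in)
        x = self.tgt_emb.forward(tgt_in) * np.sqrt(self.d_model) + self.pos[:T]
        x = self.emb_drop_tgt.forward(x.astype(self.dtype), train)
        for layer in self.dec_layers:
            x = layer.forward(x, enc_out, self_mask, enc_mask, train)
        return self.out_proj.forward(self.dec_ln.forward(x))

    def forward(self, src_ids: np.ndarray, tgt_in: np.ndarray, train: bool = False) -> np.ndarray:
        enc_out, enc_mask = self.encode(src_ids, train)
        return self.decode(enc_out, enc_mask, tgt_in, train)

    # -- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.dec_ln.backward(self.out_proj.backward(dlogits))
        d_enc = None
        for layer in reversed(self.dec_layers):
            dx, de = layer.backward(dx)
            d_enc = de if d_enc is None else d_enc + de
        dx = self.emb_drop_tgt.backward(dx)
        self.tgt_emb.backward(dx * np.sqrt(self.d_model))

        dx = self.enc_ln.backward(d_enc)
        for layer in reversed(self.enc_layers):
            dx = layer.backward(dx)
        dx = self.emb_drop_src.backward(dx)
        self.src_emb.backward(dx * np.sqrt(self.d_model))

    def zero_grads(self) -> None:
        for t in self.tensors():
            t.grad[...] = 0.0

    # -- serialization ------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [t.data for t in self.tensors()]

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        tensors = self.tensors()
        if len(arrays) != len(tensors):
            raise ValueError("weight count mismatch")
        for t, a in zip(tensors, arrays):
            if t.data.shape != a.shape:
                raise ValueError(f"shape mismatch {t.data.shape} vs {a.shape}")
            t.data[...] = a


def label_smoothed_loss(
    logits: np.ndarray, targets: np.ndarray, pad_id: int, smoothing: float
) -> tuple[float, np.ndarray, float]:
    """Label-smoothed cross-entropy, averaged over non-pad target tokens.

    Returns (loss, dlogits, token_accuracy).
    """
    B, T, V = logits.shape
    mask = (targets != pad_id).astype(logits.dtype)
    n_tok = max(mask.sum(), 1.0)
    logp = logits - logits.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    p = np.exp(logp)
    conf = 1.0 - smoothing
    nll = -np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    loss = (conf * nll - smoothing * logp.mean(axis=-1)) * mask
    target_dist = np.full_like(p, smoothing / V)
    np.put_along_axis(
        target_dist,
        targets[..., None],
        np.take_along_axis(target_dist, targets[..., None], axis=-1) + conf,
        axis=-1,
    )
    dlogits = (p - target_dist) * mask[..., None] / n_tok
    acc = float(((logits.argmax(axis=-1) == targets) * mask).sum() / n_tok)
    return float(loss.sum() / n_tok), dlogits, acc


class Adam:
    def __init__(self, tensors: list[Tensor], beta1=0.9, beta2=0.98, eps=1e-9):
        self.tensors = tensors
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, tns in enumerate(self.tensors):
            g = tns.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            tns.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def noam_lr(step: int, d_model: int, warmup: int, factor: float = 1.0) -> float:
    """Inverse-square-root schedule with linear warmup."""
    step = max(step, 1)
    return factor * d_model**-0.5 * min(step**-0.5, step * warmup**-1.5)
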