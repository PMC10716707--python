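"""Vision-Transformer building blocks: multi-head self-attention,
pre-norm encoder blocks, and a patch-embedding ViT head that consumes a
convolutional feature map and returns a pooled embedding vector."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Dense, Dropout, GELU, Layer, LayerNorm, Param


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)

    def params(self):
        out = []
        for name, sub in (("q", self.wq), ("k", self.wk),
                          ("v", self.wv), ("o", self.wo)):
            out.extend((f"{name}.{pn}", p) for pn, p in sub.params())
        return out

    def _split(self, x):  # (N,T,D) -> (N,H,T,dh)
        n, t, _ = x.shape
        return x.reshape(n, t, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N,H,T,dh) -> (N,T,D)
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, train=False):
        q = self._split(self.wq.forward(x, train))
        k = self._split(self.wk.forward(x, train))
        v = self._split(self.wv.forward(x, train))
        scale = 1.0 / np.sqrt(self.head_dim)
        attn = _softmax(np.einsum("nhtd,nhsd->nhts", q, k) * scale)
        ctx = np.einsum("nhts,nhsd->nhtd", attn, v)
        self._cache = (q, k, v, attn, scale)
        return self.wo.forward(self._merge(ctx), train)

    def backward(self, dy):
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.wo.backward(dy))
        dattn = np.einsum("nhtd,nhsd->nhts", dctx, v)
        dv = np.einsum("nhts,nhtd->nhsd", attn, dctx)
        dscore = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dq = np.einsum("nhts,nhsd->nhtd", dscore, k) * scale
        dk = np.einsum("nhts,nhtd->nhsd", dscore, q) * scale
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


class EncoderBlock(Layer):
    """Pre-norm transformer encoder block with residual connections."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 dropout: float, rng: np.random.Generator):
        hidden = int(round(dim * mlp_ratio))
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Dense(dim, hidden, rng)
        self.act = GELU()
        self.fc2 = Dense(hidden, dim, rng)
        self.drop2 = Dropout(dropout, rng)

    def params(self):
        out = []
        for name, sub in (("ln1", self.ln1), ("attn", self.attn),
                          ("ln2", self.ln2), ("fc1", self.fc1),
                          ("fc2", self.fc2)):
            out.extend((f"{name}.{pn}", p) for pn, p in sub.params())
        return out

    def forward(self, x, train=False):
        h = x + self.drop1.forward(
            self.attn.forward(self.ln1.forward(x, train), train), train)
        y = h + self.drop2.forward(
            self.fc2.forward(self.act.forward(
                self.fc1.forward(self.ln2.forward(h, train), train),
                train), train), train)
        return y

    def backward(self, dy):
        dh = dy + self.ln2.backward(self.fc1.backward(
            self.act.backward(self.fc2.backward(self.drop2.backward(dy)))))
        dx = dh + self.ln1.backward(
            self.attn.backward(self.drop1.backward(dh)))
        return dx


@dataclass(frozen=True)
class ViTConfig:
    patch_size: int = 7
    embed_dim: int = 128
    depth: int = 4
    heads: int = 4
    mlp_ratio: float = 2.0
    dropout: float = 0.1
    pooling: str = "cls"   # "cls" or "mean"

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.pooling not in ("cls", "mean"):
            raise ValueError("pooling must be 'cls' or 'mean'")


class ViT(Layer):
    """Patch embedding + positional embeddings (+ optional class token)
    -> stacked encoder blocks -> pooled embedding vector."""

    def __init__(self, cfg: ViTConfig, in_shape: tuple[int, int, int],
                 rng: np.random.Generator):
        c, h, w = in_shape
        p = cfg.patch_size
        if h % p or w % p:
            raise ValueError(
                f"feature map {h}x{w} not divisible by patch size {p}")
        self.cfg = cfg
        self.in_shape = in_shape
        self.grid = (h // p, w // p)
        self.n_tokens = self.grid[0] * self.grid[1]
        self.embed = Dense(c * p * p, cfg.embed_dim, rng)
        n_pos = self.n_tokens + (1 if cfg.pooling == "cls" else 0)
        self.pos = Param(rng.normal(0.0, 0.02, size=(n_pos, cfg.embed_dim)))
        self.cls = (Param(rng.normal(0.0, 0.02, size=(cfg.embed_dim,)))
                    if cfg.pooling == "cls" else None)
        self.blocks = [EncoderBlock(cfg.embed_dim, cfg.heads, cfg.mlp_ratio,
                                    cfg.dropout, rng)
                       for _ in range(cfg.depth)]
        self.ln = LayerNorm(cfg.embed_dim)

    def params(self):
        out = [("embed.w", self.embed.w), ("embed.b", self.embed.b),
               ("pos", self.pos)]
        if self.cls is not None:
            out.append(("cls", self.cls))
        for i, blk in enumerate(self.blocks):
            out.extend((f"block{i}.{pn}", p) for pn, p in blk.params())
        out.extend((f"ln.{pn}", p) for pn, p in self.ln.params())
        return out

    def _patchify(self, x):
        n, c, h, w = x.shape
        p = self.cfg.patch_size
        gh, gw = self.grid
        t = x.reshape(n, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        return t.reshape(n, gh * gw, c * p * p)

    def _unpatchify(self, dt):
        n = dt.shape[0]
        c, h, w = self.in_shape
        p = self.cfg.patch_size
        gh, gw = self.grid
        t = dt.reshape(n, gh, gw, c, p, p).transpose(0, 3, 1, 4, 2, 5)
        return t.reshape(n, c, h, w)

    def forward(self, x, train=False):
        n = x.shape[0]
        tok = self.embed.forward(self._patchify(x), train)
        if self.cls is not None:
            cls = np.broadcast_to(self.cls.value, (n, 1, self.cfg.embed_dim))
            tok = np.concatenate([cls, tok], axis=1)
        tok = tok + self.pos.value
        for blk in self.blocks:
            tok = blk.forward(tok, train)
        tok = self.ln.forward(tok, train)
        if self.cfg.pooling == "cls":
            self._pool_t = tok.shape[1]
            return tok[:, 0, :]
        self._pool_t = tok.shape[1]
        return tok.mean(axis=1)

    def backward(self, dy):
        n, d = dy.shape
        t = self._pool_t
        if self.cfg.pooling == "cls":
            dtok = np.zeros((n, t, d))
            dtok[:, 0, :] = dy
        else:
            dtok = np.broadcast_to(dy[:, None, :] / t, (n, t, d)).copy()
        dtok = self.ln.backward(dtok)
        for blk in reversed(self.blocks):
            dtok = blk.backward(dtok)
        self.pos.grad += dtok.reshape(-1, t, d).sum(axis=0)
        if self.cls is not None:
            self.cls.grad += dtok[:, 0, :].sum(axis=0)
            dtok = dtok[:, 1:, :]
        return self._unpatchify(self.embed.backward(dtok))
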