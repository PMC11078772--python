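"""Conditional transformer decoder over gene-expression conditioning rows.

The conditioning matrix G0 has one cell-line row followed by one row per
gene (979 rows at the default 978 genes): the cell one-hot and each gene's
raw numeric embedding are linearly projected to the hidden size, then passed
through a shared linear layer and a two-layer feed-forward block (ReLU on
the first layer).  Keeping every gene as its own row is what makes
per-gene cross-attention attribution possible downstream.

Each decoder layer applies masked multi-head self-attention over the
molecule tokens, multi-head cross-attention with the molecule states as
queries and the G0 rows as keys/values, and a position-wise feed-forward
block — each wrapped in a residual connection and layer normalization
(post-norm by default, pre-norm available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, softmax
from .nn import (Adam, Dropout, Embedding, LayerNorm, Linear, Module,
                 PerGeneLinear, sinusoidal_positions)
from .schemes import EmbeddingScheme, get_scheme

_NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the reference setting
    (hidden 64, 6 layers, 8 heads, feed-forward 512)."""

    vocab_size: int
    d: int = 64
    n_layers: int = 6
    n_heads: int = 8
    d_ff: int = 512
    gene_count: int = 978
    n_cell_lines: int = 14
    scheme: str = "tenfold_binary"
    max_len: int = 96
    dropout: float = 0.1
    positional_encoding: bool = True
    pre_norm: bool = False
    per_gene_projection: bool = False
    onehot_int_buckets: int = 52

    def __post_init__(self):
        for name in ("vocab_size", "d", "n_layers", "n_heads", "d_ff",
                     "gene_count", "n_cell_lines", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.d % self.n_heads != 0:
            raise ValueError("hidden size d must be divisible by n_heads")

    @property
    def embedding_scheme(self) -> EmbeddingScheme:
        return get_scheme(self.scheme, self.onehot_int_buckets)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelConfig":
        return cls(**payload)


@dataclass
class AttentionRecord:
    """Cross-attention weights for one molecule: (n_layers, n_heads, L, S).

    S = gene_count + 1 conditioning positions; column 0 is the cell token.
    Every (layer, head, position) row is a probability distribution.
    """

    weights: np.ndarray
    n_tokens: int  # non-PAD molecule positions (queries actually used)
    gene_count: int = field(default=978)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 4:
            raise ValueError("weights must be (n_layers, n_heads, L, S)")
        if self.weights.shape[-1] != self.gene_count + 1:
            raise ValueError("last axis must be gene_count + 1")
        if not 0 < self.n_tokens <= self.weights.shape[2]:
            raise ValueError("n_tokens out of range")
        rows = self.weights[:, :, :self.n_tokens, :].sum(axis=-1)
        if np.any(np.abs(rows - 1.0) > 1e-5) or np.any(self.weights < -1e-12):
            raise ValueError("attention rows must be normalized distributions")


class MultiHeadAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None):
        """mask: additive, broadcastable to (B, 1, Lq, Lk); returns
        (output (B, Lq, d), attention weights ndarray (B, H, Lq, Lk))."""
        B, Lq = query.shape[0], query.shape[1]
        Lk = key.shape[1]
        q = self._split(self.wq(query), B, Lq)
        k = self._split(self.wk(key), B, Lk)
        v = self._split(self.wv(value), B, Lk)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        out = attn @ v
        out = out.transpose((0, 2, 1, 3)).reshape(B, Lq, self.n_heads * self.d_head)
        return self.wo(out), attn.data

    # incremental-decoding support (exact under causal masking) ---------
    def project_kv(self, x: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """Key/value head projections as plain arrays (B, H, L, d_head)."""
        B, L = x.shape[0], x.shape[1]
        return (self._split(self.wk(x), B, L).data,
                self._split(self.wv(x), B, L).data)

    def attend_cached(self, query: Tensor, k: np.ndarray,
                      v: np.ndarray) -> Tensor:
        """Single-query attention over cached keys/values (Lq == 1)."""
        B = query.shape[0]
        q = self._split(self.wq(query), B, 1)
        scores = q @ Tensor(np.swapaxes(k, -1, -2)) * (1.0 / np.sqrt(self.d_head))
        out = softmax(scores, axis=-1) @ Tensor(v)
        out = out.transpose((0, 2, 1, 3)).reshape(B, 1, self.n_heads * self.d_head)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d, d_ff, rng)
        self.lin2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class GeneExpressionEncoder(Module):
    """Cell one-hot + per-gene raw numeric vectors -> G0 (B, G+1, d)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        scheme = cfg.embedding_scheme
        self.cell_linear = Linear(cfg.n_cell_lines, cfg.d, rng)
        if cfg.per_gene_projection:
            self.value_linear = PerGeneLinear(cfg.gene_count, scheme.raw_dim,
                                              cfg.d, rng)
        else:
            self.value_linear = Linear(scheme.raw_dim, cfg.d, rng)
        self.shared_linear = Linear(cfg.d, cfg.d, rng)
        self.ffn = FeedForward(cfg.d, cfg.d_ff, rng)

    def __call__(self, cell_onehot: np.ndarray, raw: np.ndarray) -> Tensor:
        vc = self.cell_linear(Tensor(cell_onehot))            # (B, d)
        B = vc.shape[0]
        vc = vc.reshape(B, 1, vc.shape[1])
        ve = self.value_linear(Tensor(raw))                   # (B, G, d)
        g = concat([vc, ve], axis=1)
        g = self.shared_linear(g)
        return g + self.ffn(g)


class DecoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(cfg.d, cfg.n_heads, rng)
        self.cross_attn = MultiHeadAttention(cfg.d, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d, cfg.d_ff, rng)
        self.ln1 = LayerNorm(cfg.d)
        self.ln2 = LayerNorm(cfg.d)
        self.ln3 = LayerNorm(cfg.d)
        self.drop = Dropout(cfg.dropout)
        self.pre_norm = cfg.pre_norm

    def __call__(self, x: Tensor, g0: Tensor, self_mask: np.ndarray,
                 rng, training: bool):
        if self.pre_norm:
            h, _ = self.self_attn(self.ln1(x), self.ln1(x), self.ln1(x),
                                  self_mask)
            x = x + self.drop(h, rng, training)
            h, cross_w = self.cross_attn(self.ln2(x), g0, g0)
            x = x + self.drop(h, rng, training)
            x = x + self.drop(self.ffn(self.ln3(x)), rng, training)
        else:
            h, _ = self.self_attn(x, x, x, self_mask)
            x = self.ln1(x + self.drop(h, rng, training))
            h, cross_w = self.cross_attn(x, g0, g0)
            x = self.ln2(x + self.drop(h, rng, training))
            x = self.ln3(x + self.drop(self.ffn(x), rng, training))
        return x, cross_w

    def step(self, x: Tensor, cache: _LayerCache) -> Tensor:
        """One new position (B, 1, d) with cached self-attention KV."""
        if self.pre_norm:
            h_in = self.ln1(x)
            cache.append(*self.self_attn.project_kv(h_in))
            x = x + self.self_attn.attend_cached(h_in, cache.self_k,
                                                 cache.self_v)
            x = x + self.cross_attn.attend_cached(self.ln2(x), cache.cross_k,
                                                  cache.cross_v)
            x = x + self.ffn(self.ln3(x))
        else:
            cache.append(*self.self_attn.project_kv(x))
            x = self.ln1(x + self.self_attn.attend_cached(x, cache.self_k,
                                                          cache.self_v))
            x = self.ln2(x + self.cross_attn.attend_cached(x, cache.cross_k,
                                                           cache.cross_v))
            x = self.ln3(x + self.ffn(x))
        return x


class _LayerCache:
    """Per-layer KV cache for incremental decoding."""

    def __init__(self, cross_k: np.ndarray, cross_v: np.ndarray):
        self.cross_k = cross_k
        self.cross_v = cross_v
        self.self_k: np.ndarray | None = None
        self.self_v: np.ndarray | None = None

    def append(self, k: np.ndarray, v: np.ndarray):
        if self.self_k is None:
            self.self_k, self.self_v = k, v
        else:
            self.self_k = np.concatenate([self.self_k, k], axis=2)
            self.self_v = np.concatenate([self.self_v, v], axis=2)


class ConditionalMoleculeDecoder(Module):
    """Full network: molecule embedding, N decoder layers, generator head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.encoder = GeneExpressionEncoder(cfg, rng)
        self.token_emb = Embedding(cfg.vocab_size, cfg.d, rng)
        self.positions = sinusoidal_positions(cfg.max_len, cfg.d) \
            if cfg.positional_encoding else np.zeros((cfg.max_len, cfg.d))
        self.layers = [DecoderLayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.out_linear = Linear(cfg.d, cfg.vocab_size, rng)
        self.drop = Dropout(cfg.dropout)

    def encode_condition(self, cell_onehot: np.ndarray,
                         raw: np.ndarray) -> Tensor:
        if raw.ndim != 3 or raw.shape[1] != self.cfg.gene_count:
            raise ValueError(
                f"raw conditioning must be (B, {self.cfg.gene_count}, "
                f"raw_dim); got {raw.shape}")
        if cell_onehot.shape != (raw.shape[0], self.cfg.n_cell_lines):
            raise ValueError("cell one-hot shape mismatch")
        return self.encoder(cell_onehot, raw)

    def forward(self, tokens: np.ndarray, g0: Tensor,
                pad_mask: np.ndarray | None = None,
                rng: np.random.Generator | None = None,
                training: bool = False):
        """tokens (B, L) int -> (logits (B, L, V) Tensor,
        cross-attention ndarray (n_layers, B, H, L, S)).

        Position t's logits predict the token at t+1 given tokens <= t.
        """
        tokens = np.asarray(tokens)
        if tokens.ndim != 2:
            raise ValueError("tokens must be a (B, L) integer array")
        if tokens.max() >= self.cfg.vocab_size or tokens.min() < 0:
            raise ValueError("token index out of vocabulary range")
        B, L = tokens.shape
        if L > self.cfg.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len")
        x = self.token_emb(tokens) + Tensor(self.positions[:L])
        x = self.drop(x, rng, training)
        causal = np.triu(np.full((L, L), _NEG_INF), k=1)[None, None]
        mask = causal
        if pad_mask is not None:  # pad_mask: (B, L) True at PAD keys
            mask = causal + np.where(pad_mask, _NEG_INF, 0.0)[:, None, None, :]
        cross = []
        for layer in self.layers:
            x, w = layer(x, g0, mask, rng, training)
            cross.append(w)
        return self.out_linear(x), np.stack(cross)

    def start_cache(self, g0: Tensor) -> list[_LayerCache]:
        """Prepare per-layer caches for incremental decoding against g0."""
        return [_LayerCache(*layer.cross_attn.project_kv(g0))
                for layer in self.layers]

    def step(self, tokens_t: np.ndarray, position: int,
             caches: list[_LayerCache]) -> np.ndarray:
        """Next-token probabilities (B, V) for the token just placed at
        ``position``; exact match of the full forward pass (eval mode)."""
        x = self.token_emb(np.asarray(tokens_t)[:, None]) + \
            Tensor(self.positions[position:position + 1])
        for layer, cache in zip(self.layers, caches):
            x = layer.step(x, cache)
        logits = self.out_linear(x).data[:, 0]
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_proba(self, tokens, g0, pad_mask=None):
        """Per-position next-token probability rows (eval mode)."""
        logits, cross = self.forward(tokens, g0, pad_mask)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True), cross

    def attention_record(self, cross: np.ndarray, sample: int,
                         n_tokens: int) -> AttentionRecord:
        return AttentionRecord(weights=cross[:, sample], n_tokens=n_tokens,
                               gene_count=self.cfg.gene_count)


def reconstruction_loss(prob_rows: np.ndarray, targets: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Mean -log p(true token) over non-PAD positions (evaluation form).

    Token-level KL divergence between the one-hot originals and the
    reconstruction distribution; the differentiable twin used in training is
    :func:`gexmol.autodiff.masked_cross_entropy`.
    """
    prob_rows = np.asarray(prob_rows, dtype=float)
    targets = np.asarray(targets)
    if prob_rows.shape[:-1] != targets.shape:
        raise ValueError("predicted rows and targets must align")
    if mask is None:
        mask = np.ones_like(targets, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    idx = np.nonzero(mask)
    p_true = prob_rows[idx + (targets[idx],)]
    return float(-np.log(np.clip(p_true, 1e-300, None)).mean())


def cell_onehot(cell_lines: list[str], registry) -> np.ndarray:
    idx = []
    for c in cell_lines:
        if c not in registry:
            raise KeyError(f"unknown cell line {c!r}")
        idx.append(list(registry).index(c))
    out = np.zeros((len(cell_lines), len(registry)))
    out[np.arange(len(cell_lines)), idx] = 1.0
    return out


def make_optimizer(model: Module, lr: float) -> Adam:
    return Adam(model.parameters(), lr=lr)
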