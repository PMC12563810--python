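"""Gated cross-attention fusion between drug-atom and protein-residue tokens.

One direction attends queries from one modality onto keys/values from the
other with scaled dot-product multi-head attention (padding keys are
masked out of the softmax), then mixes the attended context ``A`` with the
projected query through a gate::

    H = alpha * A + (1 - alpha) * Proj(Q)

``alpha`` is a fixed scalar (``static``), 0.5 (``averaged``), or a
per-token sigmoid output of a small gate network (``dynamic``).  Token
outputs of each direction are max-pooled (window = pooling size) and
mean-reduced into a fixed-width vector; the concatenation of both sides
is the fused representation ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .layers import Linear, Module, maxpool1d

__all__ = ["AttentionBundle", "MultiHeadCrossAttention", "GatedFusion",
           "GCABlock", "masked_pool"]

GATING_MODES = ("static", "averaged", "dynamic")
_NEG = -1e9


@dataclass
class AttentionBundle:
    A: Tensor                      # attended output (B, L_q, D_H)
    att_map: np.ndarray            # (B, h, L_q, L_k) softmax weights
    alpha: Tensor | float          # gate value(s)
    H: Tensor | None = None        # gated output (B, L_q, D_H)
    extras: dict = field(default_factory=dict)


class MultiHeadCrossAttention(Module):
    def __init__(self, query_dim: int, key_dim: int, hidden_dim: int,
                 n_heads: int, rng: np.random.Generator):
        super().__init__()
        if hidden_dim % n_heads != 0:
            raise ValueError(
                f"hidden dim {hidden_dim} not divisible by {n_heads} heads"
            )
        self.wq = Linear(query_dim, hidden_dim, rng, bias=False)
        self.wk = Linear(key_dim, hidden_dim, rng, bias=False)
        self.wv = Linear(key_dim, hidden_dim, rng, bias=False)
        self.out = Linear(hidden_dim, hidden_dim, rng)
        self.n_heads = n_heads
        self.head_dim = hidden_dim // n_heads
        self.hidden_dim = hidden_dim

    def _split_heads(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        return x.reshape(B, L, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, keys: Tensor,
                 key_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        """Returns (A, att) with att of shape (B, h, L_q, L_k)."""
        q = self._split_heads(self.wq(query))
        k = self._split_heads(self.wk(keys))
        v = self._split_heads(self.wv(keys))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        if key_mask is not None:
            bias = (1.0 - key_mask.astype(float)) * _NEG  # (B, L_k)
            scores = scores + Tensor(bias[:, None, None, :])
        att = scores.softmax(axis=-1)
        context = att @ v                                  # (B, h, L_q, d_h)
        B, _, Lq, _ = context.shape
        merged = context.transpose(0, 2, 1, 3).reshape(B, Lq, self.hidden_dim)
        return self.out(merged), att


class GatedFusion(Module):
    def __init__(self, query_dim: int, hidden_dim: int, rng: np.random.Generator,
                 mode: str = "dynamic", static_alpha: float = 0.5):
        super().__init__()
        if mode not in GATING_MODES:
            raise ValueError(f"gating mode must be one of {GATING_MODES}, got {mode!r}")
        if mode == "static" and not (0.0 < static_alpha < 1.0):
            raise ValueError(f"static alpha must lie in (0, 1), got {static_alpha}")
        self.proj = Linear(query_dim, hidden_dim, rng)
        self.gate_net = Linear(2 * hidden_dim, 1, rng)
        self.mode = mode
        self.static_alpha = static_alpha

    def alpha_for(self, attended: Tensor, projected_query: Tensor) -> Tensor | float:
        if self.mode == "static":
            return self.static_alpha
        if self.mode == "averaged":
            return 0.5
        gate_in = concat([attended, projected_query], axis=-1)
        return self.gate_net(gate_in).sigmoid()   # (B, L_q, 1), in (0, 1)

    def __call__(self, attended: Tensor, query: Tensor) -> tuple[Tensor, Tensor | float]:
        projected = self.proj(query)
        alpha = self.alpha_for(attended, projected)
        fused = alpha * attended + (1.0 - alpha) * projected
        return fused, alpha


class GCABlock(Module):
    """One attention direction plus its gate."""

    def __init__(self, query_dim: int, key_dim: int, hidden_dim: int, n_heads: int,
                 rng: np.random.Generator, gating_mode: str = "dynamic",
                 static_alpha: float = 0.5):
        super().__init__()
        self.attention = MultiHeadCrossAttention(query_dim, key_dim, hidden_dim,
                                                 n_heads, rng)
        self.gate = GatedFusion(query_dim, hidden_dim, rng, gating_mode, static_alpha)

    def __call__(self, query: Tensor, keys: Tensor,
                 key_mask: np.ndarray | None = None) -> AttentionBundle:
        attended, att = self.attention(query, keys, key_mask)
        fused, alpha = self.gate(attended, query)
        return AttentionBundle(A=attended, att_map=att.data, alpha=alpha, H=fused)


def masked_pool(tokens: Tensor, mask: np.ndarray, window: int) -> Tensor:
    """Max-pool over tokens (window, stride = ``window``) then mean over the
    pooled positions that contain at least one real token.  Returns (B, D)."""
    m = mask.astype(float)[..., None]                  # (B, L, 1)
    guarded = tokens * Tensor(m) + Tensor((1.0 - m) * _NEG)
    pooled = maxpool1d(guarded, window)                # (B, L', D)
    B, L = mask.shape
    remainder = (-L) % window
    padded_mask = np.pad(m, ((0, 0), (0, remainder), (0, 0)))
    pooled_mask = padded_mask.reshape(B, -1, window, 1).max(axis=2)  # (B, L', 1)
    counts = pooled_mask.sum(axis=1)                   # (B, 1)
    return (pooled * Tensor(pooled_mask)).sum(axis=1) * Tensor(1.0 / counts)
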