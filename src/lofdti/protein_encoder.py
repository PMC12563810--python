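"""Residue-level protein encoder: token embedding, linear projection, and
residual 1-D convolution blocks with multi-scale kernels.

A residual block computes ``Y = ReLU(F(X) + G(X))`` where F stacks 1-D
convolutions (kernel widths 3, 6 and 9 in series by default), each with
mask-aware batch normalization, ReLU and dropout, and G is a linear
dimension-matching shortcut.  Same-padding keeps the residue count fixed
through every block.  Setting ``use_residual=False`` removes the shortcut
(plain-CNN ablation).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .chem_io import PROTEIN_ALPHABET
from .layers import Conv1d, Dropout, Embedding, Linear, MaskedBatchNorm, Module

__all__ = ["ResidualBlock", "ProteinEncoder"]

ALPHABET_SIZE = len(PROTEIN_ALPHABET)


class ResidualBlock(Module):
    def __init__(
        self,
        dim: int,
        kernel_sizes: list[int],
        rng: np.random.Generator,
        dropout: float = 0.1,
        use_residual: bool = True,
    ):
        super().__init__()
        self.convs = [Conv1d(dim, dim, k, rng) for k in kernel_sizes]
        self.norms = [MaskedBatchNorm(dim) for _ in kernel_sizes]
        self.dropouts = [Dropout(dropout, rng) for _ in kernel_sizes]
        self.shortcut = Linear(dim, dim, rng, bias=False)
        self.use_residual = use_residual

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        m = Tensor(mask)
        h = x
        for conv, norm, drop in zip(self.convs, self.norms, self.dropouts):
            h = drop(norm(conv(h * m), mask).relu())
        h = h * m
        if self.use_residual:
            h = h + self.shortcut(x)
        return h.relu() * m


class ProteinEncoder(Module):
    """Token indices -> residue-level embeddings (length preserved)."""

    def __init__(
        self,
        latent_dim: int,
        n_blocks: int,
        kernel_sizes: list[int],
        rng: np.random.Generator,
        dropout: float = 0.1,
        use_residual: bool = True,
    ):
        super().__init__()
        self.embedding = Embedding(ALPHABET_SIZE, latent_dim, rng)
        self.input_proj = Linear(latent_dim, latent_dim, rng, bias=False)
        self.blocks = [
            ResidualBlock(latent_dim, kernel_sizes, rng, dropout, use_residual)
            for _ in range(n_blocks)
        ]
        self.latent_dim = latent_dim

    def embed_and_project(self, indices: np.ndarray, mask: np.ndarray) -> Tensor:
        if indices.max(initial=0) >= ALPHABET_SIZE:
            raise IndexError(
                f"token index {int(indices.max())} outside alphabet of size {ALPHABET_SIZE}"
            )
        x = self.embedding(indices)
        return (x @ self.input_proj.weight).relu() * Tensor(mask)

    def __call__(self, indices: np.ndarray, mask: np.ndarray) -> Tensor:
        """indices: (B, L) ints; mask: (B, L, 1) float. Returns (B, L, D_p)."""
        h = self.embed_and_project(indices, mask)
        for block in self.blocks:
            h = block(h, mask)
        return h
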