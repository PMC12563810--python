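"""Graph encoder for drugs: linear projection, stacked GIN layers, and
jumping-knowledge aggregation.

Each GIN layer updates a node by ``MLP((1 + eps) * h_v + sum_{u in N(v)} h_u)``
followed by mask-aware batch normalization and ReLU.  The outputs of all
layers are concatenated and linearly projected back to the latent width
(jumping knowledge), so every node embedding mixes receptive fields of
all depths.  A mean-aggregation GCN layer is available as an ablation
drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Parameter, Tensor, concat
from .chem_io import FEATURE_DIM, BatchedGraphs
from .layers import MLP, Linear, MaskedBatchNorm, Module

__all__ = ["DrugEmbedding", "GINLayer", "GCNLayer", "DrugEncoder"]


@dataclass
class DrugEmbedding:
    H0: Tensor                     # (B, N, D_d) initial projection
    per_layer: list[Tensor] = field(default_factory=list)   # K x (B, N, D_d)
    h_JK: Tensor | None = None     # (B, N, D_d)


class GINLayer(Module):
    """Sum-aggregation GIN update with learnable epsilon."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.mlp = MLP([dim, dim, dim], rng)
        self.eps = Parameter(np.zeros(1))
        self.norm = MaskedBatchNorm(dim)

    def __call__(self, h: Tensor, adjacency: np.ndarray, mask: np.ndarray) -> Tensor:
        neighbor_sum = Tensor(adjacency) @ h
        updated = self.mlp((1.0 + self.eps) * h + neighbor_sum)
        return self.norm(updated, mask).relu()


class GCNLayer(Module):
    """Degree-normalized mean-aggregation layer (ablation drop-in for GIN)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(dim, dim, rng)
        self.norm = MaskedBatchNorm(dim)

    def __call__(self, h: Tensor, adjacency: np.ndarray, mask: np.ndarray) -> Tensor:
        degree = adjacency.sum(axis=-1, keepdims=True) + 1.0  # self-loop
        agg = (Tensor(adjacency) @ h + h) * (1.0 / degree)
        return self.norm(self.linear(agg), mask).relu()


class DrugEncoder(Module):
    """74-dim raw atom features -> node-level drug embeddings."""

    def __init__(
        self,
        latent_dim: int,
        n_layers: int,
        rng: np.random.Generator,
        variant: str = "gin",
        use_jk: bool = True,
    ):
        super().__init__()
        if n_layers < 1:
            raise ValueError("need at least one graph layer")
        if variant not in ("gin", "gcn"):
            raise ValueError(f"unknown drug encoder variant {variant!r}")
        self.input_proj = Linear(FEATURE_DIM, latent_dim, rng, bias=False)
        layer_cls = GINLayer if variant == "gin" else GCNLayer
        self.layers = [layer_cls(latent_dim, rng) for _ in range(n_layers)]
        self.use_jk = use_jk
        self.jk_proj = (Linear(n_layers * latent_dim, latent_dim, rng, bias=False)
                        if use_jk else None)
        self.latent_dim = latent_dim

    def project_initial(self, features: np.ndarray, mask: np.ndarray) -> Tensor:
        """H0 = ReLU(X W0); bias-free so dummy rows stay exactly zero."""
        if features.shape[-1] != FEATURE_DIM:
            raise ValueError(
                f"expected {FEATURE_DIM} raw features, got {features.shape[-1]}"
            )
        return (Tensor(features) @ self.input_proj.weight).relu() * Tensor(mask)

    def __call__(self, batch: BatchedGraphs) -> DrugEmbedding:
        mask = batch.mask[..., None].astype(float)
        h = self.project_initial(batch.features, mask)
        emb = DrugEmbedding(H0=h)
        for layer in self.layers:
            h = layer(h, batch.adjacency, mask)
            emb.per_layer.append(h)
        if self.use_jk:
            emb.h_JK = concat(emb.per_layer, axis=-1) @ self.jk_proj.weight
            emb.h_JK = emb.h_JK * Tensor(mask)
        else:
            emb.h_JK = emb.per_layer[-1]
        return emb
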