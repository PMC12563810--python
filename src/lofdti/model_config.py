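"""Model hyperparameter configuration.

Defaults reproduce the reference settings: Adam, learning rate 1e-5,
100 epochs, batch 64, 2 residual blocks, 4 GIN layers, CNN kernels
[3, 6, 9], 4 attention heads, pooling size 3.  Ablation switches
(``use_jk``, ``use_residual``, ``use_gca``, ``encoder_variant``,
``gating_mode``, ``use_kmer``, ``bidirectional``, ``n_heads``) select the
reduced model variants without code changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    # optimization (reference defaults)
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    max_epochs: int = 100
    batch_size: int = 64
    # architecture
    n_residual_blocks: int = 2
    n_gin_layers: int = 4
    kernel_sizes: tuple[int, ...] = (3, 6, 9)
    n_heads: int = 4
    pool_size: int = 3
    drug_dim: int = 128
    protein_dim: int = 128
    hidden_dim: int = 128
    dropout: float = 0.1
    # fusion / gating
    gating_mode: str = "dynamic"        # static | averaged | dynamic
    static_alpha: float = 0.5
    bidirectional: bool = True
    # k-mer branch
    use_kmer: bool = True
    kmer_k: int = 3
    kmer_dim: int = 128
    kmer_trainable: bool = True         # dynamic vs static random projection
    # ablation switches
    use_jk: bool = True
    use_residual: bool = True
    use_gca: bool = True
    encoder_variant: str = "gin"        # gin | gcn
    # bookkeeping
    max_nodes: int | None = 128
    seed: int = 0

    def __post_init__(self):
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.gating_mode not in ("static", "averaged", "dynamic"):
            raise ValueError(f"unknown gating mode {self.gating_mode!r}")
        if self.encoder_variant not in ("gin", "gcn"):
            raise ValueError(f"unknown encoder variant {self.encoder_variant!r}")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} must be divisible by "
                f"n_heads {self.n_heads}"
            )
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
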