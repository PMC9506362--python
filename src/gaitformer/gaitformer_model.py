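"""Plain transformer encoder over flattened pose tokens.

Each normalized skeleton frame flattens to a 54-d vector (18 joints x
(x, y, c)) which a learnable affine layer projects to d_model = 256. A
learnable positional table (one row per frame position, added, not
concatenated) injects temporal order; a stack of standard post-norm
encoder layers (8-head self-attention, 2-layer feed-forward, biases
everywhere, no dropout) processes the sequence; temporal mean pooling
yields one vector per sequence. Three heads hang off the pooled vector:

* embedding head, 256 -> 256: the identity representation used (after l2
  normalization) for recognition;
* projection head, 256 -> 128: input to the supervised contrastive loss;
* appearance head, 256 -> 42 with a sigmoid: soft-label attribute
  predictions (attached to the final 256-d embedding).

Three stock sizes are provided: SM / MD / XL with 4 / 8 / 12 encoder
layers (about 2.24M / 4.35M / 6.46M trainable parameters with the default
feed-forward width of 512).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .skeleton_core import TOKEN_DIM


@dataclass
class ModelConfig:
    n_layers: int = 4
    d_model: int = 256
    n_heads: int = 8
    ff_dim: int = 512
    max_len: int = 48
    in_dim: int = TOKEN_DIM
    emb_dim: int = 256
    proj_dim: int = 128
    n_attributes: int = 42

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.n_layers, self.max_len, self.ff_dim) <= 0:
            raise ValueError("n_layers, max_len and ff_dim must be positive")


#: stock sizes (number of encoder layers)
PRESETS = {"sm": 4, "md": 8, "xl": 12}


def preset_config(name: str, **overrides) -> ModelConfig:
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return ModelConfig(n_layers=PRESETS[key], **overrides)


@dataclass
class ModelOutputs:
    embedding: nn.Tensor     # (B, emb_dim)
    projection: nn.Tensor    # (B, proj_dim)
    attributes: nn.Tensor    # (B, n_attributes), sigmoid probabilities


class GaitFormer(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.input_proj = nn.Linear(config.in_dim, config.d_model, rng)
        self.pos_table = nn.Parameter(
            rng.normal(0.0, 0.02, size=(config.max_len, config.d_model)))
        self.layers = [nn.TransformerEncoderLayer(config.d_model, config.n_heads,
                                                  config.ff_dim, rng)
                       for _ in range(config.n_layers)]
        self.embedding_head = nn.Linear(config.d_model, config.emb_dim, rng)
        self.projection_head = nn.Linear(config.emb_dim, config.proj_dim, rng)
        self.appearance_head = nn.Linear(config.emb_dim, config.n_attributes, rng)

    def __call__(self, tokens) -> ModelOutputs:
        return self.forward(tokens)

    def forward(self, tokens) -> ModelOutputs:
        """tokens: (B, T, 54) with T <= max_len. Deterministic (no dropout)."""
        x = tokens if isinstance(tokens, nn.Tensor) else nn.Tensor(tokens)
        B, T, D = x.shape
        if D != self.config.in_dim:
            raise ValueError(f"token dim {D} != {self.config.in_dim}")
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        h = self.input_proj(x) + self.pos_table[:T]
        for layer in self.layers:
            h = layer(h)
        pooled = h.mean(axis=1)                     # temporal mean pooling
        embedding = self.embedding_head(pooled)
        projection = self.projection_head(embedding)
        attributes = self.appearance_head(embedding).sigmoid()
        return ModelOutputs(embedding=embedding, projection=projection,
                            attributes=attributes)


def build(config: ModelConfig | str, seed: int = 0, **overrides) -> GaitFormer:
    """Build a model from a :class:`ModelConfig` or a preset name."""
    if isinstance(config, str):
        config = preset_config(config, **overrides)
    return GaitFormer(config, seed=seed)


def count_parameters(model: GaitFormer) -> int:
    """Total number of trainable scalar parameters."""
    return model.num_parameters()


def save_checkpoint(model: GaitFormer, path) -> None:
    state = model.state_dict()
    meta = {f"__cfg_{k}": v for k, v in asdict(model.config).items()}
    np.savez(path, **state, **meta)


def load_checkpoint(path) -> GaitFormer:
    archive = np.load(path)
    cfg_kwargs = {k[len("__cfg_"):]: archive[k].item()
                  for k in archive.files if k.startswith("__cfg_")}
    config = ModelConfig(**{k: int(v) if isinstance(v, (int, np.integer)) else v
                            for k, v in cfg_kwargs.items()})
    model = GaitFormer(config)
    model.load_state_dict({k: archive[k] for k in archive.files
                           if not k.startswith("__cfg_")})
    return model
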