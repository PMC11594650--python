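"""Dual-branch ΔΔG regression network.

Architecture: per-residue protein-language-model features for the mutant
window enter two branches.  The ESM-2-class stream (181×1280 by default) is
reduced by two nonlinear fully connected layers, given sinusoidal positional
encoding, and passed through a stack of Transformer encoder layers followed
by a linear projection to a 181×256 map; the mutation-site row (256 values)
is extracted.  The ProtT5-class stream (181×1024) is reduced to a 181×256
map that is read as a single-channel 2-D image by a multiscale convolution
module — three blocks of parallel 3×3/5×5/7×7 convolution → ReLU → batch
norm → 2×2 max-pool sub-layers with channel concatenation — then globally
average-pooled and projected to a 512-vector.  The two feature vectors are
concatenated and passed through a 256→128→1 fully connected head with
dropout, yielding the predicted ΔΔG in kcal/mol.

Each stream's processing mode is switchable (passthrough / encoder /
multiscale_conv / off) to realise the ablation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2dSame,
    Dropout,
    Linear,
    Module,
    ModuleList,
    Tensor,
    TransformerEncoderLayer,
    concat,
    relu,
)

__all__ = [
    "ModelConfig",
    "BranchOutput",
    "positional_encoding",
    "PassthroughBranch",
    "EncoderBranch",
    "MultiscaleConvBranch",
    "DualBranchNetwork",
    "BRANCH_MODES",
]

BRANCH_MODES = ("passthrough", "encoder", "multiscale_conv", "off")

_MODE_ALIASES = {"p": "passthrough", "ep": "encoder", "m": "multiscale_conv",
                 "off": "off", "passthrough": "passthrough", "encoder": "encoder",
                 "multiscale_conv": "multiscale_conv"}


def normalize_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode.lower()]
    except KeyError:
        raise ValueError(f"unknown branch mode {mode!r}; expected one of {BRANCH_MODES}") from None


@dataclass(frozen=True)
class ModelConfig:
    """Architectural and training hyperparameters.

    Defaults are the published operating point: 2 encoder layers at
    d_model=512 with 4 attention heads, 3×/5×/7× convolution kernels over
    3 blocks, a 256/128/1 fusion head, dropout 0.3, L2 1e-3, lr 1e-4.
    """

    # encoder branch
    num_layers: int = 2
    d_model: int = 512
    num_heads: int = 4
    encoder_out_dim: int = 256
    ffn_dim: Optional[int] = None  # defaults to 2*d_model
    # convolution branch
    conv_kernels: tuple[int, ...] = (3, 5, 7)
    conv_blocks: int = 3
    conv_channels: tuple[int, ...] = (8, 16, 32)  # per scale, per block
    conv_map_dim: int = 256  # feature width of the single-channel image
    conv_out_dim: int = 512
    # fusion head
    head_widths: tuple[int, ...] = (256, 128, 1)
    # regularisation / optimisation
    dropout_rate: float = 0.3
    l2_reg: float = 1e-3
    lr: float = 1e-4
    # input geometry
    esm_dim: int = 1280
    pt_dim: int = 1024
    window_len: int = 181
    # ablation branch modes
    esm_branch_mode: str = "encoder"
    pt_branch_mode: str = "multiscale_conv"

    def __post_init__(self):
        if self.d_model % self.num_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by num_heads={self.num_heads}"
            )
        if self.head_widths[-1] != 1:
            raise ValueError("head_widths must end in 1 (scalar ΔΔG output)")
        for name in ("num_layers", "d_model", "num_heads", "encoder_out_dim",
                     "conv_map_dim", "conv_out_dim", "window_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.conv_channels) != self.conv_blocks:
            raise ValueError("conv_channels must list one width per conv block")
        object.__setattr__(self, "esm_branch_mode", normalize_mode(self.esm_branch_mode))
        object.__setattr__(self, "pt_branch_mode", normalize_mode(self.pt_branch_mode))
        if self.esm_branch_mode == "off" and self.pt_branch_mode == "off":
            raise ValueError("at least one branch must be active")

    @classmethod
    def desk_scale(cls, esm_dim: int = 32, pt_dim: int = 24,
                   window_len: int = 31, **overrides) -> "ModelConfig":
        """Width-reduced configuration for CPU-scale studies.

        Same architecture (two encoder layers, four heads, three multiscale
        convolution blocks, two-layer stems, three-layer fusion head) at a
        fraction of the width, sized for the synthetic desk-scale benchmark:
        d_model 32, 16-dim encoder output, 24-wide convolution image with
        2/4/8 channels per scale.  Dropout is reduced to 0.1 and the L2
        coefficient to 1e-5 — at these widths the published rates, tuned for
        512-wide layers, suppress learning entirely — and the learning rate
        is raised to 2e-3 to converge within a small epoch budget.
        """
        defaults = dict(
            d_model=32, num_heads=4, encoder_out_dim=16, ffn_dim=64,
            conv_map_dim=24, conv_channels=(2, 4, 8), conv_out_dim=32,
            head_widths=(32, 16, 1), dropout_rate=0.1, l2_reg=1e-5, lr=2e-3,
            esm_dim=esm_dim, pt_dim=pt_dim, window_len=window_len,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def ffn_width(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 2 * self.d_model

    def with_modes(self, esm_mode: str, pt_mode: str) -> "ModelConfig":
        return replace(self, esm_branch_mode=esm_mode, pt_branch_mode=pt_mode)

    def stem_hidden(self, d_in: int, d_out: int) -> int:
        """Width of the intermediate layer of a two-layer reduction stem.

        The published reductions are 1280→768→512 and 1024→512→256; both are
        the midpoint of input and output width, which is what we use for
        arbitrary dimensions.
        """
        return max(1, (d_in + d_out) // 2)

    def feature_dim(self, mode: str) -> int:
        mode = normalize_mode(mode)
        if mode == "off":
            return 0
        return self.conv_out_dim if mode == "multiscale_conv" else self.encoder_out_dim


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal positional-encoding table (length × dim), entries in [−1, 1].

    entry(pos, 2i) = sin(pos / 10000^(2i/dim)); entry(pos, 2i+1) = cos(same).
    """
    if length < 1 or dim < 1:
        raise ValueError("length and dim must be >= 1")
    pos = np.arange(length)[:, None]
    i2 = np.arange(0, dim, 2)
    angle = pos / np.power(10000.0, i2 / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : dim // 2])
    return pe


@dataclass
class BranchOutput:
    """Fixed-length feature vector of one branch (batched), plus the
    per-position map for branches that produce one."""

    feature_vector: Tensor  # (B, branch_dim)
    aux_matrix: Optional[Tensor] = None  # (B, L, encoder_out_dim) when present


def _site_rows(x: Tensor, local_index: np.ndarray) -> Tensor:
    B = x.shape[0]
    return x[np.arange(B), np.asarray(local_index, dtype=int)]


class PassthroughBranch(Module):
    """Dimensionality reduction only: two nonlinear fully connected layers
    applied per position; the mutation-site row is the branch feature."""

    def __init__(self, d_in: int, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hidden = config.stem_hidden(d_in, config.encoder_out_dim)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, config.encoder_out_dim, rng)

    def __call__(self, x: Tensor, local_index: np.ndarray) -> BranchOutput:
        h = relu(self.fc2(relu(self.fc1(x))))
        return BranchOutput(_site_rows(h, local_index), aux_matrix=h)


class EncoderBranch(Module):
    """Reduction stem → positional encoding → Transformer encoder stack →
    linear projection to the per-position output map; the site row is the
    branch feature."""

    def __init__(self, d_in: int, config: ModelConfig, rng: np.random.Generator,
                 rng_ref: dict):
        super().__init__()
        hidden = config.stem_hidden(d_in, config.d_model)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, config.d_model, rng)
        self._pe = positional_encoding(config.window_len, config.d_model)
        self.layers = ModuleList(
            TransformerEncoderLayer(config.d_model, config.num_heads, config.ffn_width,
                                    config.dropout_rate, rng, rng_ref)
            for _ in range(config.num_layers)
        )
        self.proj = Linear(config.d_model, config.encoder_out_dim, rng)

    def __call__(self, x: Tensor, local_index: np.ndarray) -> BranchOutput:
        h = relu(self.fc2(relu(self.fc1(x))))
        h = h + Tensor(self._pe[: h.shape[1]].astype(h.data.dtype, copy=False))
        for layer in self.layers:
            h = layer(h)
        aux = self.proj(h)
        return BranchOutput(_site_rows(aux, local_index), aux_matrix=aux)


class MultiscaleConvBranch(Module):
    """Reduction stem to an L×conv_map_dim map read as a one-channel image,
    then ``conv_blocks`` blocks of parallel multi-kernel sub-layers
    (convolution → ReLU → batch norm → 2×2 max-pool, channel-concatenated),
    global average pooling and a fully connected output layer."""

    def __init__(self, d_in: int, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        from .nn import maxpool2x2  # local alias to keep forward tight

        self._pool = maxpool2x2
        hidden = config.stem_hidden(d_in, config.conv_map_dim)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, config.conv_map_dim, rng)
        self.convs = ModuleList()
        self.bns = ModuleList()
        in_ch = 1
        for block, ch in zip(range(config.conv_blocks), config.conv_channels):
            for k in config.conv_kernels:
                self.convs.append(Conv2dSame(in_ch, ch, k, rng))
                self.bns.append(BatchNorm2d(ch))
            in_ch = ch * len(config.conv_kernels)
        self.n_scales = len(config.conv_kernels)
        self.n_blocks = config.conv_blocks
        self.out = Linear(in_ch, config.conv_out_dim, rng)

    def __call__(self, x: Tensor, local_index: np.ndarray = None) -> BranchOutput:
        h = relu(self.fc2(relu(self.fc1(x))))  # (B, L, map)
        B, L, M = h.shape
        img = h.reshape(B, 1, L, M)
        idx = 0
        for _ in range(self.n_blocks):
            outs = []
            for _ in range(self.n_scales):
                y = self._pool(self.bns[idx](relu(self.convs[idx](img))))
                outs.append(y)
                idx += 1
            img = concat(outs, axis=1)
        pooled = img.mean(axis=(2, 3))  # global average pooling over positions
        return BranchOutput(self.out(pooled))


class FusionHead(Module):
    """Concatenated branch features → nonlinear fully connected layers with
    dropout → scalar ΔΔG."""

    def __init__(self, d_in: int, config: ModelConfig, rng: np.random.Generator,
                 rng_ref: dict):
        super().__init__()
        widths = config.head_widths
        self.fcs = ModuleList()
        self.drops = ModuleList()
        prev = d_in
        for w in widths:
            self.fcs.append(Linear(prev, w, rng))
            self.drops.append(Dropout(config.dropout_rate, rng_ref))
            prev = w

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.fcs)
        for i in range(n):
            x = self.fcs[i](x)
            if i < n - 1:  # final layer is the linear ΔΔG readout
                x = self.drops[i](relu(x))
        return x


def _build_branch(mode: str, d_in: int, config: ModelConfig,
                  rng: np.random.Generator, rng_ref: dict) -> Optional[Module]:
    mode = normalize_mode(mode)
    if mode == "off":
        return None
    if mode == "passthrough":
        return PassthroughBranch(d_in, config, rng)
    if mode == "encoder":
        return EncoderBranch(d_in, config, rng, rng_ref)
    return MultiscaleConvBranch(d_in, config, rng)


class DualBranchNetwork(Module):
    """Full ΔΔG regressor: two feature streams, one fusion head.

    ``forward(E, P, local_index)`` takes the ESM-class batch (B, L, esm_dim),
    the ProtT5-class batch (B, L, pt_dim) and the 0-based mutation-site
    indices, and returns a (B,) tensor of ΔΔG estimates.  A stream whose
    mode is ``off`` may be passed as ``None``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = np.dtype(dtype)
        self._rng_ref = {"rng": np.random.default_rng(seed)}
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.esm_branch = _build_branch(config.esm_branch_mode, config.esm_dim,
                                        config, rng, self._rng_ref)
        self.pt_branch = _build_branch(config.pt_branch_mode, config.pt_dim,
                                       config, rng, self._rng_ref)
        fused = (config.feature_dim(config.esm_branch_mode)
                 + config.feature_dim(config.pt_branch_mode))
        self.head = FusionHead(fused, config, rng, self._rng_ref)
        if self.dtype != np.float64:
            self.astype(self.dtype)

    def reset_rng(self, seed: int) -> None:
        """Reseed the dropout-mask stream (training reproducibility)."""
        self._rng_ref["rng"] = np.random.default_rng(seed)

    def forward(self, E: Optional[np.ndarray | Tensor],
                P: Optional[np.ndarray | Tensor],
                local_index: np.ndarray) -> Tensor:
        feats = []
        if self.esm_branch is not None:
            if E is None:
                raise ValueError("ESM-stream input required by the configured mode")
            x = E if isinstance(E, Tensor) else Tensor(E)
            feats.append(self.esm_branch(x, local_index).feature_vector)
        if self.pt_branch is not None:
            if P is None:
                raise ValueError("ProtT5-stream input required by the configured mode")
            x = P if isinstance(P, Tensor) else Tensor(P)
            feats.append(self.pt_branch(x, local_index).feature_vector)
        fused = feats[0] if len(feats) == 1 else concat(feats, axis=-1)
        return self.head(fused).reshape(fused.shape[0])

    __call__ = forward

    def predict(self, E, P, local_index, batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode ΔΔG predictions as a plain array."""
        was_training = self.training
        self.eval()
        out = []
        n = len(local_index)
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            out.append(self.forward(None if E is None else E[lo:hi],
                                    None if P is None else P[lo:hi],
                                    local_index[lo:hi]).data)
        if was_training:
            self.train()
        return np.concatenate(out)

    def l2_penalty(self) -> Tensor:
        """Sum of squared weight-matrix entries (biases and norms excluded)."""
        total = Tensor(np.zeros(()))
        for mod in self.modules():
            if isinstance(mod, (Linear, Conv2dSame)):
                w = mod.weight
                total = total + (w * w).sum()
        return total
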