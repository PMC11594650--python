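"""Neural-network layers built on the autodiff engine.

Initialisation is fan-in-scaled and fully determined by the generator each
layer receives, so a network built twice from the same seed has identical
parameters.  Layers with stochastic or batch-dependent behaviour (dropout,
batch normalisation) follow the usual train/eval convention.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d_same, relu, softmax_lastdim

__all__ = [
    "Module",
    "Parameter",
    "ModuleList",
    "Linear",
    "Dropout",
    "LayerNorm",
    "BatchNorm2d",
    "Conv2dSame",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for mod in self._modules.values():
            out.extend(mod.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mname, mod in self._modules.items():
            out.extend(mod.named_parameters(prefix + mname + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for mod in self._modules.values():
            out.extend(mod.modules())
        return out

    def train(self, mode: bool = True):
        for mod in self.modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus persistent buffers, in module order."""
        arrays = [p.data for p in self.parameters()]
        for mod in self.modules():
            arrays.extend(getattr(mod, "_buffers", {}).values())
        return arrays

    def copy_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def astype(self, dtype):
        """Convert all parameters and buffers in place (e.g. to float32)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for mod in self.modules():
            buffers = getattr(mod, "_buffers", None)
            if buffers:
                for k in buffers:
                    buffers[k] = buffers[k].astype(dtype)
        return self

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(own, arrays):
            dst[...] = src


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._items))] = mod
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _fan_in_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.weight = Parameter(_fan_in_init(rng, d_in, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; draws masks from a generator owned by the network."""

    def __init__(self, p: float, rng_ref: dict):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._rng_ref = rng_ref  # shared {"rng": Generator}; reseedable by the owner

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self._rng_ref["rng"].random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype, copy=False))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, H, W); normalise per channel
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
            xc = x - mu
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Conv2dSame(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_fan_in_init(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_same(x, self.weight, self.bias)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``num_heads`` parallel heads."""

    def __init__(self, d_model: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % num_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by num_heads={num_heads}")
        self.num_heads = num_heads
        self.d_head = d_model // num_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        # (B, L, D) -> (B, H, L, dh)
        return x.reshape(B, L, self.num_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax_lastdim(scores)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention and feed-forward sub-layers, each
    wrapped in dropout, a residual connection and layer normalisation."""

    def __init__(self, d_model: int, num_heads: int, ffn_dim: int,
                 dropout: float, rng: np.random.Generator, rng_ref: dict):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, num_heads, rng)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng_ref)
        self.drop2 = Dropout(dropout, rng_ref)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ffn2(relu(self.ffn1(x)))))
        return x
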