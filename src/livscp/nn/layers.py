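"""Neural-network building blocks on top of the autograd engine.

Initialization follows the training recipe used throughout the package:
convolution-like layers (the patch embedding) use Kaiming-normal fan-in
initialization, plain linear layers use Xavier-uniform, and normalization
layers start at scale one / shift zero.

Each module carries a ``qmode`` flag (``"fp32" | "fp16" | "int8"``) used
only at inference time: ``fp16`` casts parameters and activations to half
precision inside linear layers; ``int8`` applies per-tensor affine
dynamic quantization (8-bit weights and activations, dequantized for the
matmul) to linear layers only, the standard CPU post-training path.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, gelu, softmax

DTYPE = np.float32


def quantize_dequantize_int8(x: np.ndarray) -> np.ndarray:
    """Per-tensor affine int8 fake-quantization (round-trip)."""
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return x.copy()
    scale = (hi - lo) / 255.0
    zero = np.round(-lo / scale)
    q = np.clip(np.round(x / scale + zero), 0, 255)
    return ((q - zero) * scale).astype(x.dtype)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True
        self.qmode = "fp32"

    # -- registry -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def set_qmode(self, mode: str) -> "Module":
        if mode not in ("fp32", "fp16", "int8"):
            raise ValueError(f"unsupported precision mode: {mode!r}")
        for m in self.modules():
            m.qmode = mode
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def checksum(self) -> str:
        """Hex digest of all parameter bytes; bit-exact freeze witness."""
        import hashlib

        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.data.shape)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def kaiming_normal(rng: np.random.Generator, fan_in: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    """Affine layer ``y = x W + b``; Xavier-uniform by default,
    Kaiming-normal when ``kaiming=True`` (convolution-equivalent layers)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, kaiming: bool = False):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        if kaiming:
            w = kaiming_normal(rng, in_features, (in_features, out_features))
        else:
            w = xavier_uniform(rng, in_features, out_features,
                               (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        if self.qmode == "fp16":
            xv = x.data.astype(np.float16)
            w = self.weight.data.astype(np.float16)
            b = self.bias.data.astype(np.float16)
            return Tensor(np.matmul(xv, w) + b)
        if self.qmode == "int8":
            xv = quantize_dequantize_int8(x.data.astype(np.float32))
            w = quantize_dequantize_int8(self.weight.data.astype(np.float32))
            return Tensor(np.matmul(xv, w) + self.bias.data.astype(np.float32))
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / ((var + self.eps) ** 0.5)
        return xhat * self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis of a 2-D input."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1).astype(DTYPE))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1).astype(DTYPE))
            xhat = xc / ((var + self.eps) ** 0.5)
        else:
            dt = x.data.dtype
            xhat = ((x - self.running_mean.astype(dt))
                    / np.sqrt(self.running_var.astype(dt) + self.eps))
        return xhat * self.weight + self.bias


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return gelu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % num_heads != 0:
            raise ValueError("dim must be divisible by num_heads")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dh = self.num_heads, self.head_dim
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, h, N, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block with a 4x GELU MLP."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, num_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Sequential(
            Linear(dim, mlp_ratio * dim, rng),
            GELU(),
            Linear(mlp_ratio * dim, dim, rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))
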