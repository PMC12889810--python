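"""Minimal numpy neural-network layer library.

Implements exactly the layers the package's three classifier
architectures need — 2-D convolution, max pooling, batch/layer
normalization, linear maps, ReLU/GELU, multi-head self-attention and a
pre-norm transformer encoder block — each as a module with an explicit
``forward``/``backward`` pair, plus softmax cross-entropy and an Adam
optimizer.  Everything is float32 and fully deterministic: weights are
drawn from a caller-supplied ``numpy.random.Generator`` and the forward
and backward passes contain no hidden randomness (no dropout).

The reverse pass is hand-derived per layer rather than traced by an
autodiff engine; gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Module", "Parameter", "Sequential", "Linear", "Conv2d", "MaxPool2d",
    "BatchNorm2d", "LayerNorm", "ReLU", "GELU", "Flatten", "GlobalAvgPool2d",
    "MultiHeadSelfAttention", "TransformerEncoderLayer",
    "softmax", "cross_entropy", "Adam",
]

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: a differentiable map with parameters and a train flag."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect_params(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=DTYPE)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch at parameter {i}: {arr.shape} vs {p.value.shape}")
            p.value = arr
            p.grad = np.zeros_like(arr)


def _collect_params(obj) -> list[Parameter]:
    if isinstance(obj, Parameter):
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect_params(item))
        return out
    return []


def _collect_modules(obj) -> list["Module"]:
    if isinstance(obj, Module):
        return obj.modules()
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect_modules(item))
        return out
    return []


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# Dense / activation layers
# ---------------------------------------------------------------------------

class Linear(Module):
    """Affine map on the last axis; Kaiming-uniform init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_features, out_features)), "linear.weight"
        )
        self.bias = Parameter(np.zeros(out_features), "linear.bias")
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.weight.grad += x2.T @ d2
        self.bias.grad += d2.sum(axis=0)
        return dout @ self.weight.value.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Module):
    """Exact Gaussian error linear unit, x * Phi(x)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2)).astype(DTYPE)
        return x * self._cdf

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return dout * (self._cdf + x * pdf).astype(DTYPE)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class GlobalAvgPool2d(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """2-D convolution via im2col; Kaiming-uniform init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, fan_in)), "conv.weight"
        )
        self.bias = Parameter(np.zeros(out_channels), "conv.bias") if bias else None

    def _out_hw(self, H: int, W: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho, Wo = self._out_hw(H, W)
        # (B, C, Ho, Wo, k, k) -> (B, Ho*Wo, C*k*k)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, C * k * k
        )
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        self._cols, self._in_hw = cols, (H, W)
        return out.transpose(0, 2, 1).reshape(B, self.out_channels, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Co, Ho, Wo = dout.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        H, W = self._in_hw
        dflat = dout.reshape(B, Co, Ho * Wo).transpose(0, 2, 1)  # (B, L, Co)
        self.weight.grad += np.einsum("blc,blf->cf", dflat, self._cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=(0, 1))
        dcols = (dflat @ self.weight.value).reshape(B, Ho, Wo, self.in_channels, k, k)
        dxp = np.zeros((B, self.in_channels, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class MaxPool2d(Module):
    """Max pooling with optional padding (padded with -inf)."""

    def __init__(self, kernel_size: int, stride: Optional[int] = None, padding: int = 0) -> None:
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        Hp, Wp = x.shape[2], x.shape[3]
        Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(B, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._arg, self._pad_hw, self._in_hw = arg, (Hp, Wp), (H, W)
        self._out_hw = (Ho, Wo)
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, Ho, Wo = dout.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        Hp, Wp = self._pad_hw
        H, W = self._in_hw
        di, dj = np.divmod(self._arg, k)  # offsets within each window
        bi = np.arange(B)[:, None, None, None]
        ci = np.arange(C)[None, :, None, None]
        ri = np.arange(Ho)[None, None, :, None] * s + di
        cj = np.arange(Wo)[None, None, None, :] * s + dj
        dxp = np.zeros((B, C, Hp, Wp), dtype=DTYPE)
        np.add.at(dxp, (bi, ci, ri, cj), dout)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features), "bn.gamma")
        self.beta = Parameter(np.zeros(num_features), "bn.beta")
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv = xhat.astype(DTYPE), inv.astype(DTYPE)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        B, C, H, W = dout.shape
        m = B * H * W
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self.training:
            return (dxhat * inv[None, :, None, None]).astype(DTYPE)
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] * (term1 - term2 - term3)).astype(DTYPE)


class LayerNorm(Module):
    """Normalization over the last axis (token features)."""

    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim), "ln.gamma")
        self.beta = Parameter(np.zeros(dim), "ln.beta")

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((x - mean) * inv).astype(DTYPE)
        self._inv = inv.astype(DTYPE)
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dout * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += dout.reshape(-1, xhat.shape[-1]).sum(axis=0)
        dxhat = dout * self.gamma.value
        mean_d = dxhat.mean(axis=-1, keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (inv * (dxhat - mean_d - xhat * mean_dx)).astype(DTYPE)


# ---------------------------------------------------------------------------
# Attention / transformer encoder
# ---------------------------------------------------------------------------

def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard multi-head scaled dot-product self-attention."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv.forward(x).reshape(B, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k_, v = qkv[0], qkv[1], qkv[2]  # each (B, h, T, hd)
        scale = 1.0 / math.sqrt(hd)
        attn = _softmax_last((q @ k_.transpose(0, 1, 3, 2)) * scale).astype(DTYPE)
        ctx = attn @ v  # (B, h, T, hd)
        out = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        self._cache = (q, k_, v, attn, scale)
        return self.proj.forward(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k_, v, attn, scale = self._cache
        B, h, T, hd = q.shape
        D = self.dim
        dctx = (
            self.proj.backward(dout).reshape(B, T, h, hd).transpose(0, 2, 1, 3)
        )
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax jacobian along last axis
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores = (dscores * scale).astype(DTYPE)
        dq = dscores @ k_
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack([dq, dk, dv])  # (3, B, h, T, hd)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(B, T, 3 * D)
        return self.qkv.backward(dqkv)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)); x + MLP(LN(x)), GELU MLP."""

    def __init__(
        self, dim: int, n_heads: int, mlp_ratio: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = Sequential(
            Linear(dim, mlp_ratio * dim, rng), GELU(), Linear(mlp_ratio * dim, dim, rng)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn.forward(self.ln1.forward(x))
        return x + self.mlp.forward(self.ln2.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout + self.ln2.backward(self.mlp.backward(dout))
        return dx + self.ln1.backward(self.attn.backward(dx))


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the last axis."""
    return _softmax_last(np.asarray(logits, dtype=np.float64))


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = len(targets)
    probs = softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(n), targets], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                DTYPE
            )
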