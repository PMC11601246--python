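"""Neural-network building blocks on top of :mod:`phenoclip.autodiff`.

Implements the layers the phenotyping model needs: 2-D convolution via
im2col, batch normalization with running statistics, layer normalization,
multi-head self-attention with key padding masks, pre-norm transformer
encoder layers, and a gradient-reversal op for domain-adversarial training.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, as_tensor, softmax

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm",
    "MultiheadAttention", "TransformerEncoderLayer", "grad_reverse", "conv2d",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, m in [("", self)] + [(n, mm) for n, mm in self._named_modules()]:
            if isinstance(m, BatchNorm2d):
                state[f"{prefix}running_mean"] = m.running_mean.copy()
                state[f"{prefix}running_var"] = m.running_var.copy()
        return state

    def _named_modules(self, prefix: str = ""):
        out = []
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                out.append((f"{prefix}{name}.", value))
                out.extend(value._named_modules(f"{prefix}{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.append((f"{prefix}{name}.{i}.", item))
                        out.extend(item._named_modules(f"{prefix}{name}.{i}."))
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = state[name].copy()
        for prefix, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"{prefix}running_mean"].copy()
                m.running_var = state[f"{prefix}running_var"].copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = math.sqrt(1.0 / d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int, padding: int) -> Tensor:
    """2-D convolution via im2col.  ``weight`` has shape (Cin*k*k, Cout)."""
    x = as_tensor(x)
    n, cin, h, w = x.shape
    k = int(round(math.sqrt(weight.shape[0] // cin)))
    if padding:
        xp = np.zeros((n, cin, h + 2 * padding, w + 2 * padding), dtype=x.data.dtype)
        xp[:, :, padding:padding + h, padding:padding + w] = x.data
    else:
        xp = x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    # (N, Ho, Wo, Cin, k, k) -> rows ordered to match weight layout (Cin, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, cin * k * k)
    out_flat = cols @ weight.data
    if bias is not None:
        out_flat = out_flat + bias.data
    out_data = out_flat.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
    req = weight.requires_grad or x.requires_grad or (bias is not None and bias.requires_grad)
    if not req:
        return Tensor(out_data)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, -1)
        if weight.requires_grad:
            weight._accum(cols.T @ gm)
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ weight.data.T).reshape(n, ho, wo, cin, k, k)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, requires_grad=True, parents=parents, backward=backward)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1, padding: int = 1):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = cin * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, cout)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)

    @staticmethod
    def output_size(size: int, kernel: int, stride: int, padding: int) -> int:
        return (size + 2 * padding - kernel) // stride + 1


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        axes = (0, 2, 3)
        cshape = (1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(cshape)) * inv_std.reshape(cshape)
        out_data = self.gamma.data.reshape(cshape) * xhat + self.beta.data.reshape(cshape)
        gamma, beta, training, eps = self.gamma, self.beta, self.training, self.eps

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gscale = gamma.data.reshape(cshape) * inv_std.reshape(cshape)
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    gmean = g.mean(axis=axes).reshape(cshape)
                    gx_mean = (g * xhat).mean(axis=axes).reshape(cshape)
                    x._accum(gscale * (g - gmean - xhat * gx_mean))
                else:
                    x._accum(gscale * g)

        req = x.requires_grad or gamma.requires_grad or beta.requires_grad
        return Tensor(out_data, requires_grad=req,
                      parents=(x, gamma, beta) if req else (),
                      backward=backward if req else None)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class MultiheadAttention(Module):
    """Self-attention over channel tokens with an optional key padding mask."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.head_dim = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None):
        """``x``: (B, T, d); ``key_mask``: (B, T) with 1 = attend, 0 = exclude.

        Returns ``(output (B, T, d), attention (B, heads, T, T))``.
        """
        b, t, d = x.shape
        h, hd = self.n_heads, self.head_dim

        def heads(proj):
            return proj(x.reshape(b * t, d)).reshape(b, t, h, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q_proj), heads(self.k_proj), heads(self.v_proj)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        if key_mask is not None:
            bias = np.where(key_mask.astype(bool), 0.0, -np.inf).astype(scores.dtype)
            scores = scores + bias[:, None, None, :]
        attn = softmax(scores, axis=-1)
        out = attn @ v
        out = out.transpose(0, 2, 1, 3).reshape(b * t, d)
        return self.out_proj(out).reshape(b, t, d), attn


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block with SiLU feed-forward."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiheadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None):
        attn_out, attn = self.attn(self.ln1(x), key_mask)
        x = x + attn_out
        b, t, d = x.shape
        hid = self.ff1(self.ln2(x).reshape(b * t, d)).silu()
        x = x + self.ff2(hid).reshape(b, t, d)
        return x, attn


def grad_reverse(x: Tensor, lam: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-lam``."""
    x = as_tensor(x)
    if not x.requires_grad:
        return Tensor(x.data)

    def backward(g):
        x._accum(-lam * g)

    return Tensor(x.data, requires_grad=True, parents=(x,), backward=backward)
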