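"""Small neural-network building blocks on the autodiff core.

Layers operate on single volumes in channel-first layout ``(C, D, H, W)``;
there is no batch axis — training loops iterate cases and accumulate
gradients, which is adequate at the volume counts this package targets.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["glorot", "Linear", "Conv3d", "avgpool2", "upsample2", "AdamW"]


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True):
        self.weight = glorot(rng, (n_in, n_out), n_in, n_out)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class Conv3d:
    """'Same'-padded 3D convolution with odd cubic kernels via im2col."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan = c_in * k**3
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.weight = glorot(rng, (c_out, c_in, k, k, k), fan, c_out * k**3)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, c_in, c_out = self.k, self.c_in, self.c_out
        pad = k // 2
        C, D, H, W = x.data.shape
        if C != c_in:
            raise ValueError(f"expected {c_in} input channels, got {C}")
        xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3)
        patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (C, D, H, W, k, k, k) -> (N, C*k^3)
        cols = patches.transpose(1, 2, 3, 0, 4, 5, 6).reshape(D * H * W, c_in * k**3)
        w_t, b_t = self.weight, self.bias
        wmat = w_t.data.reshape(c_out, -1)
        out_data = (cols @ wmat.T + b_t.data).reshape(D, H, W, c_out).transpose(3, 0, 1, 2)

        def backward(g):
            g_n = g.transpose(1, 2, 3, 0).reshape(D * H * W, c_out)
            grad_w = (g_n.T @ cols).reshape(w_t.data.shape)
            grad_b = g_n.sum(axis=0)
            gc = (g_n @ wmat).reshape(D, H, W, c_in, k, k, k)
            grad_xp = np.zeros_like(xp)
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        grad_xp[:, a:a + D, b:b + H, c:c + W] += gc[..., a, b, c].transpose(3, 0, 1, 2)
            grad_x = grad_xp[:, pad:pad + D, pad:pad + H, pad:pad + W]
            return (grad_x, grad_w, grad_b)

        return Tensor._make(out_data, (x, w_t, b_t), backward)

    def params(self):
        return [self.weight, self.bias]


def avgpool2(x: Tensor) -> Tensor:
    """2x downsampling mean pool; spatial dims must be even."""
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    out_data = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2).mean(axis=(2, 4, 6))

    def backward(g):
        g_up = np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2), 2, axis=3)
        return (g_up / 8.0,)

    return Tensor._make(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out_data = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), 2, axis=3)
    C, D, H, W = x.data.shape

    def backward(g):
        return (g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6)),)

    return Tensor._make(out_data, (x,), backward)


class AdamW:
    """AdamW with decoupled weight decay (betas per the training setup)."""

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.95),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)
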