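"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for a small U-Net trained on modest tile sizes:
3×3 'same' convolutions via im2col/col2im, ReLU, 2×2 max pooling,
nearest-neighbour upsampling, channel concatenation and an Adam optimiser.
Arrays are ``(N, C, H, W)`` float64.  Every layer implements
``forward(x)`` and ``backward(grad_out) -> grad_in``, storing parameter
gradients in ``.grads`` aligned with ``.params``.

Gradients are verified against central finite differences in the test
suite, so the layers can be trusted as building blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "UpsampleNearest2",
    "Adam",
    "sigmoid",
    "iou_bce_loss",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k×k 'same' convolution (zero padding), He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, Wd = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * Wd, C * k * k)
        self._cols = cols
        self._xshape = x.shape
        Wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wmat.T + self.b
        return out.transpose(0, 2, 1).reshape(N, -1, H, Wd)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, Wd = self._xshape
        k, p = self.k, self.k // 2
        out_ch = grad.shape[1]
        g = grad.reshape(N, out_ch, H * Wd).transpose(0, 2, 1)  # (N, HW, out)
        Wmat = self.W.reshape(out_ch, -1)
        self.grads[0][...] = (
            np.einsum("nio,nif->of", g, self._cols).reshape(self.W.shape)
        )
        self.grads[1][...] = g.sum(axis=(0, 1))
        dcols = g @ Wmat  # (N, HW, C*k*k)
        dcols = dcols.reshape(N, H, Wd, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, Wd + 2 * p))
        for dy in range(k):
            for dx in range(k):
                dxp[:, :, dy : dy + H, dx : dx + Wd] += dcols[:, :, :, :, dy, dx].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + H, p : p + Wd]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (
            (flat & first)
            .reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
        )
        return out

    def backward(self, grad):
        g = grad[:, :, :, None, :, None] * self._mask
        N, C, Hh, _, Wh, _ = g.shape
        return g.reshape(N, C, Hh * 2, Wh * 2)


class UpsampleNearest2(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        N, C, H, W = grad.shape
        return grad.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def iou_bce_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1e-7):
    """Combined loss L = L_IoU + L_CE on sigmoid probabilities.

    The IoU term is the soft (differentiable) Jaccard loss over the
    foreground: 1 − Σpy / Σ(p + y − py), which is 0 exactly when the
    probabilities match a one-hot target.  The cross-entropy term is the
    mean binary cross entropy.  Returns ``(loss, dL/dlogits)``.
    """
    p = sigmoid(logits)
    y = targets
    n = p.size
    pc = np.clip(p, eps, 1 - eps)
    bce = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    inter = float((p * y).sum())
    union = float((p + y - p * y).sum())
    if union < eps:  # no foreground anywhere and p ~ 0: perfect agreement
        iou_loss = 0.0
        d_iou_dp = np.zeros_like(p)
    else:
        iou_loss = 1.0 - inter / union
        d_iou_dp = -(y * union - inter * (1.0 - y)) / union**2
    dbce_dlogit = (p - y) / n
    dloss = dbce_dlogit + d_iou_dp * p * (1.0 - p)
    return bce + iou_loss, dloss
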