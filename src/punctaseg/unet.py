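"""A compact 2.5D U-Net for neurite masking.

The network consumes a stack chunk of ``depth`` consecutive slices and
predicts the segmentation of the centre slice only — the neighbouring
slices act as 3D context without the memory cost of a full 3D model.  The
depth axis is collapsed by the first convolution (the seven slices enter
as input channels), after which the network is a standard encoder–decoder
with skip connections: per level two 3×3 conv + ReLU blocks, 2×2 max
pooling on the way down, nearest-neighbour upsampling and skip
concatenation on the way up, and a 1×1 convolution producing one logit
map.  Feature widths double per level.
"""

from __future__ import annotations

import numpy as np

from .nn import Adam, Conv2d, MaxPool2, ReLU, UpsampleNearest2, sigmoid

__all__ = ["UNet25D"]


class _ConvBlock:
    def __init__(self, in_ch, out_ch, rng):
        self.layers = [Conv2d(in_ch, out_ch, rng=rng), ReLU(), Conv2d(out_ch, out_ch, rng=rng), ReLU()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet25D:
    """Encoder–decoder over depth-as-channels input.

    Parameters
    ----------
    depth:
        Number of input slices per chunk (the centre slice is predicted).
    base:
        Feature maps at the top level; doubled at each of ``levels`` levels.
    levels:
        Number of resolution levels (pooling steps = levels − 1).  Input
        tiles must be divisible by ``2**(levels-1)``.
    """

    def __init__(self, depth: int = 7, base: int = 8, levels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth, self.base, self.levels, self.seed = depth, base, levels, seed
        widths = [base * 2**i for i in range(levels)]
        self.enc = []
        in_ch = depth
        for w in widths:
            self.enc.append(_ConvBlock(in_ch, w, rng))
            in_ch = w
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.ups = [UpsampleNearest2() for _ in range(levels - 1)]
        self.dec = []
        for i in range(levels - 2, -1, -1):
            self.dec.append(_ConvBlock(widths[i + 1] + widths[i], widths[i], rng))
        self.head = Conv2d(widths[0], 1, k=1, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def _conv_layers(self):
        convs = []
        for block in self.enc + self.dec:
            convs.extend(l for l in block.layers if isinstance(l, Conv2d))
        convs.append(self.head)
        return convs

    @property
    def params(self):
        return [p for c in self._conv_layers() for p in c.params]

    @property
    def grads(self):
        return [g for c in self._conv_layers() for g in c.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, self.grads, lr=lr)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """``x``: (N, depth, H, W) → logits (N, 1, H, W)."""
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h)
            if i < self.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, block in enumerate(self.dec):
            h = self.ups[i].forward(h)
            skip = skips[-(i + 1)]
            h = block.forward(np.concatenate([skip, h], axis=1))
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        # dec[i] consumed concat(skips[levels-2-i], upsampled), so walk the
        # decoder in reverse and split each gradient back into its two paths
        for i in range(len(self.dec) - 1, -1, -1):
            g = self.dec[i].backward(g)
            s_idx = self.levels - 2 - i
            n_skip = self._skip_channels[s_idx]
            skip_grads[s_idx] = g[:, :n_skip]
            g = self.ups[i].backward(g[:, n_skip:])
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability map (N, H, W) for the centre slice of each chunk."""
        return sigmoid(self.forward(x))[:, 0]

    # -- persistence ---------------------------------------------------------
    def state(self) -> dict:
        out = {"depth": self.depth, "base": self.base, "levels": self.levels, "seed": self.seed}
        for i, p in enumerate(self.params):
            out[f"param_{i}"] = p
        return out

    @classmethod
    def from_state(cls, state: dict) -> "UNet25D":
        net = cls(
            depth=int(state["depth"]),
            base=int(state["base"]),
            levels=int(state["levels"]),
            seed=int(state["seed"]),
        )
        net.set_weights([state[f"param_{i}"] for i in range(len(net.params))])
        return net
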