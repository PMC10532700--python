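"""Minimal 3D U-Net in numpy for desk-scale volumetric segmentation.

The architecture follows the common encoder/decoder pattern: five blocks
of 3x3x3 convolutions with leaky-ReLU activations, each followed by 2x2x2
max-pooling, filter counts doubling from ``base_filters``; a mirrored
decoder with nearest-neighbour upsampling and skip concatenation; and a
1x1x1 head with softmax (multi-class) or sigmoid (binary) output.

Everything — forward pass, backpropagation, Adam — is implemented with
numpy matmuls (im2col).  The network is resolution-agnostic; training at
clinical resolution is out of scope here and the implementation targets
small grids (e.g. 32 cubed).
"""

from __future__ import annotations

import numpy as np

from .errors import MisuseError

_LEAKY_SLOPE = 0.1


# -- primitive layers -------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(D,H,W,C) -> (D*H*W, 27*C) patches of the zero-padded input."""
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(0, 1, 2))
    # win: (D,H,W,C,3,3,3) -> (N, 3,3,3,C) -> (N, 27C)
    win = win.transpose(0, 1, 2, 4, 5, 6, 3)
    return win.reshape(-1, 27 * x.shape[-1])


class Conv3x3:
    """Same-padded 3x3x3 convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (27 * cin))
        self.W = rng.normal(0, scale, size=(27 * cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        y = self._cols @ self.W + self.b
        return y.reshape(*x.shape[:3], self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy.reshape(-1, self.cout)
        self.gW = self._cols.T @ g
        self.gb = g.sum(axis=0)
        # input gradient = correlation of gy with the spatially flipped,
        # channel-transposed kernel
        Wk = self.W.reshape(3, 3, 3, self.cin, self.cout)
        Wf = Wk[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3).reshape(27 * self.cout, self.cin)
        cols = _im2col(gy)
        gx = cols @ Wf
        self._cols = None
        return gx.reshape(*self._shape)

    def params(self):
        return [(self.W, "gW"), (self.b, "gb")]


class Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0, np.sqrt(2.0 / cin), size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW = self._x.reshape(-1, self.cin).T @ gy.reshape(-1, self.cout)
        self.gb = gy.reshape(-1, self.cout).sum(axis=0)
        return gy @ self.W.T

    def params(self):
        return [(self.W, "gW"), (self.b, "gb")]


class LeakyReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, _LEAKY_SLOPE * x, x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, _LEAKY_SLOPE * gy, gy)


class MaxPool2:
    """2x2x2 max pooling (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, h, w, c = x.shape
        self._shape = x.shape
        blocks = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
        blocks = blocks.transpose(0, 2, 4, 1, 3, 5, 6).reshape(d // 2, h // 2, w // 2, 8, c)
        self._arg = blocks.argmax(axis=3)
        return np.take_along_axis(blocks, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d, h, w, c = self._shape
        g = np.zeros((d // 2, h // 2, w // 2, 8, c), dtype=gy.dtype)
        np.put_along_axis(g, self._arg[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        g = g.reshape(d // 2, h // 2, w // 2, 2, 2, 2, c).transpose(0, 3, 1, 4, 2, 5, 6)
        return g.reshape(d, h, w, c)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d, h, w, c = gy.shape
        return gy.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


# -- the network ------------------------------------------------------------


class UNet3D:
    """Five-block 3D U-Net; ``final`` is ``"softmax"`` or ``"sigmoid"``."""

    def __init__(self, n_classes: int, in_channels: int = 1, base_filters: int = 16,
                 depth: int = 5, final: str = "softmax", seed: int = 0):
        if final not in ("softmax", "sigmoid"):
            raise MisuseError("final activation must be 'softmax' or 'sigmoid'")
        if final == "sigmoid" and n_classes != 1:
            raise MisuseError("sigmoid head implies a single output channel")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.final = final
        self.n_classes = n_classes
        filters = [base_filters * 2 ** i for i in range(depth)]

        self.enc, self.pools = [], []
        cin = in_channels
        for f in filters:
            self.enc.append((Conv3x3(cin, f, rng), LeakyReLU()))
            self.pools.append(MaxPool2())
            cin = f
        self.dec = []
        dec_filters = list(reversed(filters[:-1])) + [filters[0]]
        for i, f in enumerate(dec_filters):
            skip_ch = filters[depth - 1 - i]
            self.dec.append((Upsample2(), Conv3x3(cin + skip_ch, f, rng), LeakyReLU()))
            cin = f
        self.head = Conv1x1(cin, n_classes, rng)

    # layers with parameters, in a stable order
    def _param_layers(self):
        return [c for c, _ in self.enc] + [c for _, c, _ in self.dec] + [self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(D,H,W) or (D,H,W,Cin) -> per-voxel class probabilities."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32)
        d = x.shape[0]
        if d % (2 ** self.depth):
            raise MisuseError(
                f"input size {x.shape[:3]} not divisible by 2^{self.depth}")
        skips = []
        for (conv, act), pool in zip(self.enc, self.pools):
            x = act.forward(conv.forward(x))
            skips.append(x)
            x = pool.forward(x)
        self._concat_ch = []
        for (up, conv, act), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x)
            self._concat_ch.append((x.shape[-1], skip.shape[-1]))
            x = act.forward(conv.forward(np.concatenate([x, skip], axis=-1)))
        z = self.head.forward(x)
        self._logits = z
        if self.final == "softmax":
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            self._probs = e / e.sum(axis=-1, keepdims=True)
        else:
            self._probs = 1.0 / (1.0 + np.exp(-z))
        return self._probs

    def backward(self, glogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits."""
        g = self.head.backward(glogits.astype(np.float32))
        gskips = []
        for (up, conv, act), (up_ch, skip_ch) in zip(reversed(self.dec),
                                                     reversed(self._concat_ch)):
            g = conv.backward(act.backward(g))
            g, gskip = g[..., :up_ch], g[..., up_ch:]
            gskips.append(gskip)
            g = up.backward(g)
        for (conv, act), pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                            reversed(gskips)):
            g = pool.backward(g) + gskip
            g = conv.backward(act.backward(g))

    def probs(self) -> np.ndarray:
        return self._probs


class Adam:
    """Adam optimizer over a UNet3D's parameters."""

    def __init__(self, net: UNet3D, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {}
        for li, layer in enumerate(net._param_layers()):
            for pi, (p, _) in enumerate(layer.params()):
                self.state[(li, pi)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for li, layer in enumerate(self.net._param_layers()):
            for pi, (p, gname) in enumerate(layer.params()):
                g = getattr(layer, gname)
                m, v = self.state[(li, pi)]
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= lr * corr * m / (np.sqrt(v) + self.eps)
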