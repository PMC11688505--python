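"""A small dilated-convolution denoising network, pure numpy.

The architecture follows the mixed-scale idea: a stack of 3x3 convolutions
whose dilation cycles through powers of two grows the receptive field
quickly at a tiny parameter count (default well under 50k), which limits
noise overfitting on the short slice stacks this pipeline trains on.  A
global residual connection (output = input + correction) makes the network
an exact identity at initialisation — the final layer starts at zero — so
training only has to learn the noise component it should remove.

Forward, backward and the Adam optimiser are implemented directly on
numpy arrays; at desk scale (64x64 slices, <10 layers, <=16 channels)
training runs comfortably on one CPU.  All randomness flows through a
caller-supplied :class:`numpy.random.Generator`, so runs are reproducible
bit-for-bit for a fixed seed on a fixed platform.

Array layout is [batch, channel, height, width] throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetConfig", "ConvNet", "Adam"]

_LEAK = 0.1  # leaky-ReLU negative slope; avoids dead units in tiny nets


@dataclass
class NetConfig:
    """Architecture recipe: ``depth`` hidden 3x3 conv layers of ``width``
    channels, dilations cycling through ``dilation_cycle``, then a 1x1
    projection back to one channel added to the input."""

    depth: int = 6
    width: int = 8
    # widening-then-closing cycle spans the long-range correlations of
    # Hilbert-reconstructed (low-frequency) noise at desk-scale image sizes
    dilation_cycle: tuple[int, ...] = (1, 2, 4, 8, 16, 1)

    def __post_init__(self) -> None:
        if self.depth < 1 or self.width < 1:
            raise ValueError("depth and width must be >= 1")
        if any(d < 1 for d in self.dilation_cycle):
            raise ValueError("dilations must be >= 1")

    def n_parameters(self) -> int:
        n = 9 * self.width + self.width  # first layer: 1 -> width
        n += (self.depth - 1) * (9 * self.width**2 + self.width)
        n += self.width + 1  # 1x1 projection
        return n


def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, dilation: int):
    """'Same' zero-padded dilated 3x3 convolution.  Returns (y, x_padded)."""
    n, _, h, wd = x.shape
    d = dilation
    xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
    y = np.empty((n, w.shape[0], h, wd), dtype=x.dtype)
    y[:] = b[None, :, None, None]
    for p in range(3):
        for q in range(3):
            patch = xp[:, :, p * d : p * d + h, q * d : q * d + wd]
            y += np.einsum("oc,nchw->nohw", w[:, :, p, q], patch, optimize=True)
    return y, xp


def _conv3x3_backward(dy: np.ndarray, xp: np.ndarray, w: np.ndarray, dilation: int):
    """Gradients of the dilated conv: returns (dx, dw, db)."""
    n, _, h, wd = dy.shape
    d = dilation
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for p in range(3):
        for q in range(3):
            patch = xp[:, :, p * d : p * d + h, q * d : q * d + wd]
            dw[:, :, p, q] = np.einsum("nohw,nchw->oc", dy, patch, optimize=True)
            dxp[:, :, p * d : p * d + h, q * d : q * d + wd] += np.einsum(
                "oc,nohw->nchw", w[:, :, p, q], dy, optimize=True
            )
    db = dy.sum(axis=(0, 2, 3))
    dx = dxp[:, :, d : d + h, d : d + wd]
    return dx, dw, db


class ConvNet:
    """Residual dilated CNN with explicit parameter list and backprop."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.dilations: list[int] = []
        c_in = 1
        for layer in range(config.depth):
            fan_in = 9 * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (config.width, c_in, 3, 3))
            self.weights.append(w)
            self.biases.append(np.zeros(config.width))
            self.dilations.append(
                config.dilation_cycle[layer % len(config.dilation_cycle)]
            )
            c_in = config.width
        # near-zero 1x1 head -> network starts near the identity while still
        # passing gradient to the hidden layers from the first step
        self.head_w = rng.normal(0.0, 1e-3, (1, config.width))
        self.head_b = np.zeros(1)

    # --- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.head_w, self.head_b]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        d = self.config.depth
        self.weights = [np.array(p) for p in params[:d]]
        self.biases = [np.array(p) for p in params[d : 2 * d]]
        self.head_w = np.array(params[2 * d])
        self.head_b = np.array(params[2 * d + 1])

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    # --- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: [batch, 1, H, W] -> same shape.  Cache for backward()."""
        cache = []
        h = x
        for w, b, d in zip(self.weights, self.biases, self.dilations):
            z, hp = _conv3x3_forward(h, w, b, d)
            a = np.where(z > 0, z, _LEAK * z)
            cache.append((hp, z))
            h = a
        y = x + np.einsum("oc,nchw->nohw", self.head_w, h) + self.head_b[None, :, None, None]
        if want_cache:
            return y, (cache, h)
        return y

    def backward(self, dy: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients w.r.t. parameters, ordered as :meth:`parameters`."""
        layer_cache, h_last = cache
        d_head_w = np.einsum("nohw,nchw->oc", dy, h_last)
        d_head_b = dy.sum(axis=(0, 2, 3))
        dh = np.einsum("oc,nohw->nchw", self.head_w, dy)

        d_weights = [None] * self.config.depth
        d_biases = [None] * self.config.depth
        for layer in reversed(range(self.config.depth)):
            hp, z = layer_cache[layer]
            dz = dh * np.where(z > 0, 1.0, _LEAK)
            dh, dw, db = _conv3x3_backward(
                dz, hp, self.weights[layer], self.dilations[layer]
            )
            d_weights[layer] = dw
            d_biases[layer] = db
        return [*d_weights, *d_biases, d_head_w, d_head_b]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


@dataclass
class Adam:
    """Adam optimiser over a parameter list."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
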