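"""Dense numpy building blocks for the interaction network.

The architecture is small enough (a projection, a 1x1 mixing layer, one
2D convolution and a pooling head) that explicit forward/backward passes
in numpy are practical on a CPU; gradients are hand-derived per block and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialisation."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def sigmoid(x):
    """Numerically stable logistic function; preserves scalar/array shape."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out[0]) if scalar else out


def conv2d_same(H: np.ndarray, Wc: np.ndarray, bc: float):
    """Single-output-channel 2D cross-correlation with zero 'same' padding.

    H: (n, m, c) feature map, Wc: (c, k, k) kernel, k odd.

    ``G[i, j] = bc + sum_{c,a,b} Hpad[i+a, j+b, c] * Wc[c, a, b]``.

    Computed in the frequency domain (cross-correlation = convolution
    with the spatially flipped kernel) at FFT-friendly transform sizes;
    the forward transform of H is cached in the returned context and
    reused by the backward pass, which needs it for the kernel gradient.
    Returns (G, ctx).
    """
    from scipy import fft as sfft

    c, k, _ = Wc.shape
    half = k // 2
    n, m, _ = H.shape
    S = (sfft.next_fast_len(n + k - 1), sfft.next_fast_len(m + k - 1))
    FH = sfft.rfft2(H, s=S, axes=(0, 1))
    Wflip = np.moveaxis(Wc, 0, -1)[::-1, ::-1, :]
    FW = sfft.rfft2(Wflip, s=S, axes=(0, 1))
    G = sfft.irfft2((FH * FW).sum(axis=2), s=S)[half:half + n, half:half + m]
    ctx = {"FH": FH, "S": S, "shape": (n, m), "k": k, "dtype": H.dtype}
    return G.astype(H.dtype) + bc, ctx


def conv2d_same_backward(dG: np.ndarray, ctx: dict, Wc: np.ndarray):
    """Gradients of conv2d_same w.r.t. kernel, bias and input.

    Reuses the cached forward transform: one FFT of the output gradient
    serves both the input gradient (convolution with the unflipped
    kernel) and the kernel gradient (circular correlation of H with the
    output gradient, read off at lags -half..half).
    """
    from scipy import fft as sfft

    c, k, _ = Wc.shape
    half = k // 2
    n, m = ctx["shape"]
    S = ctx["S"]
    FdG = sfft.rfft2(dG, s=S)
    FWu = sfft.rfft2(np.moveaxis(Wc, 0, -1), s=S, axes=(0, 1))
    dH = sfft.irfft2(FdG[:, :, None] * FWu, s=S, axes=(0, 1))[
        half:half + n, half:half + m, :]
    T = sfft.irfft2(ctx["FH"] * np.conj(FdG)[:, :, None], s=S, axes=(0, 1))
    ia = [(a - half) % S[0] for a in range(k)]
    ib = [(b - half) % S[1] for b in range(k)]
    dWc = np.moveaxis(T[np.ix_(ia, ib)], -1, 0)
    dbc = float(dG.sum())
    dt = ctx["dtype"]
    return dWc.astype(dt), dbc, dH.astype(dt)


def maxpool2d(C: np.ndarray, width: int):
    """Non-overlapping block max-pooling; trailing partial blocks kept.

    Returns the pooled map and the flat argmax index of each block for
    gradient routing.
    """
    n, m = C.shape
    nb = -(-n // width)
    mb = -(-m // width)
    Q = np.empty((nb, mb))
    arg = np.empty((nb, mb), dtype=np.int64)
    for i in range(nb):
        for j in range(mb):
            r0, r1 = i * width, min((i + 1) * width, n)
            c0, c1 = j * width, min((j + 1) * width, m)
            block = C[r0:r1, c0:c1]
            a = int(np.argmax(block))
            br, bc_ = divmod(a, c1 - c0)
            Q[i, j] = block[br, bc_]
            arg[i, j] = (r0 + br) * m + (c0 + bc_)
    return Q, arg


def maxpool2d_backward(dQ: np.ndarray, arg: np.ndarray, shape: tuple) -> np.ndarray:
    dC = np.zeros(shape[0] * shape[1])
    np.add.at(dC, arg.ravel(), dQ.ravel())
    return dC.reshape(shape)


class Adam:
    """Adam optimizer over a dict of named numpy parameters."""

    def __init__(self, params: dict, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
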