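"""Minimal neural-network core for the planning agent.

Implements exactly what the actor/critic architectures need — 3D
convolutions (kernel 3, stride 1, padding 1), ReLU, a global-average-pool
linear head, and Adam — with hand-written backpropagation. The convolution
inner loops are JIT-compiled with numba so training stays practical on a
single CPU core at the volumetric state sizes involved. Everything is
float32 and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["Conv3d", "ReLU", "GlobalAvgPoolLinear", "Adam", "ActorNet", "CriticNet"]


@njit(cache=True, fastmath=True)
def _conv3d_same(xp: np.ndarray, W: np.ndarray, b: np.ndarray, y: np.ndarray) -> np.ndarray:
    """y[b,co] = b[co] + sum_ci W[co,ci] * xp[b,ci] (valid conv on padded input)."""
    B, CO, D, H, Wd = y.shape
    C = xp.shape[1]
    for bi in range(B):
        for co in range(CO):
            for d in range(D):
                for h in range(H):
                    row = y[bi, co, d, h]
                    for w in range(Wd):
                        row[w] = b[co]
                    for ci in range(C):
                        for i in range(3):
                            for j in range(3):
                                base = xp[bi, ci, d + i, h + j]
                                for k in range(3):
                                    wk = W[co, ci, i, j, k]
                                    for w in range(Wd):
                                        row[w] += wk * base[w + k]
    return y


@njit(cache=True, fastmath=True)
def _conv3d_grads(xp: np.ndarray, dy: np.ndarray, dW: np.ndarray, db: np.ndarray) -> None:
    """Accumulate weight/bias gradients from padded input and output gradient."""
    B, CO, D, H, Wd = dy.shape
    C = xp.shape[1]
    for co in range(CO):
        for bi in range(B):
            for d in range(D):
                for h in range(H):
                    row = dy[bi, co, d, h]
                    s = np.float32(0.0)
                    for w in range(Wd):
                        s += row[w]
                    db[co] += s
                    for ci in range(C):
                        for i in range(3):
                            for j in range(3):
                                base = xp[bi, ci, d + i, h + j]
                                for k in range(3):
                                    acc = np.float32(0.0)
                                    for w in range(Wd):
                                        acc += row[w] * base[w + k]
                                    dW[co, ci, i, j, k] += acc


def _pad(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


class Conv3d:
    """3D convolution, kernel 3, stride 1, padding 1 (shape-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        fan_in = in_channels * 27
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(out_channels, in_channels, 3, 3, 3)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._xp: np.ndarray | None = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        xp = _pad(np.ascontiguousarray(x, dtype=np.float32))
        self._xp = xp
        B, _, D2, H2, W2 = xp.shape
        y = np.empty((B, self.out_channels, D2 - 2, H2 - 2, W2 - 2), dtype=np.float32)
        _conv3d_same(xp, self.W, self.b, y)
        return y

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        _conv3d_grads(self._xp, dy, dW, db)
        # dx: full correlation of dy with the spatially flipped, transposed kernel
        w_flip = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        dx = np.empty((dy.shape[0], self.in_channels) + dy.shape[2:], dtype=np.float32)
        _conv3d_same(_pad(dy), w_flip, np.zeros(self.in_channels, np.float32), dx)
        return dx, [dW, db]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list]:
        return np.where(self._mask, dy, 0.0).astype(np.float32), []


class GlobalAvgPoolLinear:
    """Global average pool over space followed by a linear map to one scalar."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 1.0 / np.sqrt(in_channels), size=in_channels).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        self._pooled: np.ndarray | None = None
        self._spatial: tuple | None = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C = x.shape[:2]
        self._spatial = x.shape[2:]
        self._pooled = x.reshape(B, C, -1).mean(axis=2)
        return self._pooled @ self.w + self.b  # (B,)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        B, C = self._pooled.shape
        n = int(np.prod(self._spatial))
        dw = dy @ self._pooled
        db = np.array([dy.sum()], dtype=np.float32)
        dpooled = np.outer(dy, self.w)  # (B, C)
        dx = np.broadcast_to(dpooled[:, :, None] / n, (B, C, n)).reshape(B, C, *self._spatial)
        return dx.astype(np.float32), [dw.astype(np.float32), db]


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Backpropagate and return parameter gradients aligned with parameters()."""
        grads_rev: list[np.ndarray] = []
        for layer in reversed(self.layers):
            dy, gs = layer.backward(dy)
            grads_rev.extend(reversed(gs))
        return list(reversed(grads_rev))

    # -- flat parameter I/O (checkpointing / tests) -----------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s


class ActorNet(_Sequential):
    """Policy network: four shape-preserving 3D convolutions mapping the
    4-channel state to one score map per collimator; the masked softmax over
    (collimator, voxel) actions is applied downstream."""

    def __init__(self, n_collimators: int = 4, hidden_channels: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        h = hidden_channels
        super().__init__(
            [
                Conv3d(4, h, rng),
                ReLU(),
                Conv3d(h, h, rng),
                ReLU(),
                Conv3d(h, h, rng),
                ReLU(),
                Conv3d(h, n_collimators, rng),
            ]
        )
        self.n_collimators = n_collimators


class CriticNet(_Sequential):
    """Value network: four 3D convolutions, global average pool, linear head."""

    def __init__(self, hidden_channels: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        h = hidden_channels
        super().__init__(
            [
                Conv3d(4, h, rng),
                ReLU(),
                Conv3d(h, h, rng),
                ReLU(),
                Conv3d(h, h, rng),
                ReLU(),
                Conv3d(h, h, rng),
                ReLU(),
                GlobalAvgPoolLinear(h, rng),
            ]
        )


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
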