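"""Numpy building blocks of the mesh autoencoder, with explicit gradients.

The only non-standard layer is the Chebyshev spectral graph convolution:
``y = sum_k T_k(L~) x W_k`` where ``T_0 = I, T_1 = L~`` and
``T_k = 2 L~ T_{k-1} - T_{k-2}`` on a Laplacian ``L~`` rescaled to spectral
range [-1, 1]. All products are sparse matrix times dense signal; no
eigendecomposition is ever performed during training. Because ``L~`` is
symmetric, the backward pass reuses the same recursion.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..mesh_core import GraphLaplacian


def _lap_apply(lap: sp.csr_matrix, x: np.ndarray) -> np.ndarray:
    """Apply an (M_out, M_in) sparse matrix to (B, M_in, F) vertex signals."""
    b, m, f = x.shape
    y = lap @ x.transpose(1, 0, 2).reshape(m, b * f)
    return y.reshape(lap.shape[0], b, f).transpose(1, 0, 2)


def _cheb_stack(lap: sp.csr_matrix, x: np.ndarray, k: int) -> list[np.ndarray]:
    """[T_0(L)x, ..., T_{k-1}(L)x] for a (B, M, F) signal batch."""
    ts = [x]
    if k > 1:
        ts.append(_lap_apply(lap, x))
    for _ in range(2, k):
        ts.append(2.0 * _lap_apply(lap, ts[-1]) - ts[-2])
    return ts


def chebyshev_filter(
    laplacian: GraphLaplacian, x: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Filter vertex signals with a Chebyshev polynomial kernel.

    Parameters
    ----------
    laplacian : scaled Laplacian (spectrum in [-1, 1])
    x : (M, F_in) or (B, M, F_in) signals
    weights : (K, F_in, F_out) per-order filter coefficients

    Returns signals of shape matching ``x`` with F_out channels.
    """
    weights = np.asarray(weights, float)
    if weights.ndim != 3 or weights.shape[0] < 1:
        raise ValueError("weights must be (K, F_in, F_out) with K >= 1")
    squeeze = False
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[None]
        squeeze = True
    if x.shape[1] != laplacian.n:
        raise ValueError("signal length does not match the Laplacian")
    if x.shape[2] != weights.shape[1]:
        raise ValueError("channel mismatch between x and weights")
    ts = _cheb_stack(laplacian.laplacian, x, weights.shape[0])
    y = sum(t @ w for t, w in zip(ts, weights))
    return y[0] if squeeze else y


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs)
# ---------------------------------------------------------------------------

class ChebConv:
    def __init__(self, lap: sp.csr_matrix, f_in: int, f_out: int, k: int, rng: np.random.Generator):
        self.lap = lap
        self.k = k
        scale = np.sqrt(2.0 / (f_in * k + f_out))
        self.w = rng.standard_normal((k, f_in, f_out)) * scale
        self.b = np.zeros(f_out)
        self._ts: list[np.ndarray] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._ts = _cheb_stack(self.lap, x, self.k)
        return sum(t @ w for t, w in zip(self._ts, self.w)) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ts = self._ts
        self.dw = np.stack([np.einsum("bmi,bmo->io", t, dy) for t in ts])
        self.db = dy.sum(axis=(0, 1))
        # adjoint of the recursion t_k = 2 L t_{k-1} - t_{k-2} (L symmetric):
        # b_k = g_k + 2 L b_{k+1} - b_{k+2}, then dx = b_0 + L b_1
        g = [dy @ self.w[k].T for k in range(self.k)]
        b_next = np.zeros_like(g[-1])
        b = g[-1]
        for k in range(self.k - 2, 0, -1):
            b, b_next = g[k] + 2.0 * _lap_apply(self.lap, b) - b_next, b
        if self.k == 1:
            return g[0]
        # after the loop b = b_1 and b_next = b_2; t_1 = Lx and t_2 feeds -t_0
        return g[0] - b_next + _lap_apply(self.lap, b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class Pool:
    """Multiply by a fixed sparse sampling matrix (down- or up-map)."""

    def __init__(self, q: sp.csr_matrix):
        self.q = q
        self.qt = q.T.tocsr()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return _lap_apply(self.q, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _lap_apply(self.qt, dy)

    def params(self):
        return []


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / (n_in + n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class Adam:
    """Standard Adam over the (name, value, grad) triples exposed by layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for name, value, grad in layer.params():
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(value), np.zeros_like(value))
                m, v = self.state[key]
                m[:] = b1 * m + (1 - b1) * grad
                v[:] = b2 * v + (1 - b2) * grad * grad
                mh = m / (1 - b1 ** self.t)
                vh = v / (1 - b2 ** self.t)
                value -= self.lr * mh / (np.sqrt(vh) + self.eps)
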