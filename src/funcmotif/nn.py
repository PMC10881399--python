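"""Minimal NumPy neural-network layers for 1-D sequence models.

Each layer exposes three passes over explicit caches (so two independent
forward states — an actual input and an attribution reference — can coexist):

* ``forward(x) -> (out, cache)``
* ``backward(dout, cache) -> (dx, param_grads)`` — ordinary gradients
* ``deeplift(m, cache, ref_cache) -> m_in`` — DeepLIFT multiplier
  propagation: the linear rule for affine layers, the rescale rule for
  elementwise nonlinearities, and the gradient path (actual-input argmax)
  for max-pooling.

Multiplying the input multipliers by (x - x_ref) yields contributions whose
sum telescopes to the output difference f(x) - f(x_ref) (summation-to-delta),
exactly for affine + rescale layers, and exactly for max-pooling whenever the
reference activations are constant within each pooling window — which holds
for the uniform-background reference used here, because a position-invariant
input yields position-invariant convolution activations.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

Cache = Dict[str, np.ndarray]

#: below this |x - x_ref| the rescale ratio falls back to the local gradient
RESCALE_EPS = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    params: Dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, Cache]:
        raise NotImplementedError

    def backward(self, dout, cache) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        raise NotImplementedError

    def deeplift(self, m, cache: Cache, ref_cache: Cache) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-mode 1-D convolution over (batch, length, channels)."""

    def __init__(self, in_channels: int, n_filters: int, width: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.width = width
        self.in_channels = in_channels
        fan_in = width * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init (ReLU follows)
        self.params = {
            "W": rng.normal(0.0, scale, size=(fan_in, n_filters)),
            "b": np.zeros(n_filters),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, L, C) -> (B, n, w*C)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # cols: (B, n, C, w) -> (B, n, w, C)
        cols = cols.transpose(0, 1, 3, 2)
        b, n = cols.shape[:2]
        return np.ascontiguousarray(cols).reshape(b, n, -1)

    def forward(self, x):
        cols = self._im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        return out, {"cols": cols, "in_shape": np.array(x.shape)}

    def _dx_from_dcols(self, dcols: np.ndarray, in_shape) -> np.ndarray:
        b, L, c = (int(v) for v in in_shape)
        n = dcols.shape[1]
        dcols = dcols.reshape(b, n, self.width, c)
        dx = np.zeros((b, L, c))
        for j in range(self.width):
            dx[:, j : j + n, :] += dcols[:, :, j, :]
        return dx

    def backward(self, dout, cache):
        cols = cache["cols"]
        W = self.params["W"]
        dW = np.einsum("bnk,bnf->kf", cols, dout)
        db = dout.sum(axis=(0, 1))
        dx = self._dx_from_dcols(dout @ W.T, cache["in_shape"])
        return dx, {"W": dW, "b": db}

    def deeplift(self, m, cache, ref_cache):
        # affine layer: multipliers propagate exactly like gradients
        return self._dx_from_dcols(m @ self.params["W"].T, cache["in_shape"])


class ReLU(Layer):
    def forward(self, x):
        return np.maximum(x, 0.0), {"x": x}

    def backward(self, dout, cache):
        return dout * (cache["x"] > 0), {}

    def deeplift(self, m, cache, ref_cache):
        x, xr = cache["x"], ref_cache["x"]
        dx = x - xr
        ratio = np.where(
            np.abs(dx) > RESCALE_EPS,
            (np.maximum(x, 0.0) - np.maximum(xr, 0.0))
            / np.where(np.abs(dx) > RESCALE_EPS, dx, 1.0),
            (x > 0).astype(float),
        )
        return m * ratio


class MaxPool1D(Layer):
    """Non-overlapping max pool over the length axis; trailing remainder dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x):
        b, L, c = x.shape
        n = L // self.pool
        xt = x[:, : n * self.pool, :].reshape(b, n, self.pool, c)
        arg = xt.argmax(axis=2)
        out = xt.max(axis=2)
        return out, {"arg": arg, "in_shape": np.array(x.shape)}

    def _route(self, dout, cache):
        b, L, c = (int(v) for v in cache["in_shape"])
        n = L // self.pool
        dxt = np.zeros((b, n, self.pool, c))
        bi, ni, ci = np.ogrid[:b, :n, :c]
        dxt[bi, ni, cache["arg"], ci] = dout
        dx = np.zeros((b, L, c))
        dx[:, : n * self.pool, :] = dxt.reshape(b, n * self.pool, c)
        return dx

    def backward(self, dout, cache):
        return self._route(dout, cache), {}

    def deeplift(self, m, cache, ref_cache):
        # gradient path: route through the actual input's argmax
        return self._route(m, cache)


class Flatten(Layer):
    def forward(self, x):
        return x.reshape(x.shape[0], -1), {"in_shape": np.array(x.shape)}

    def backward(self, dout, cache):
        return dout.reshape([int(v) for v in cache["in_shape"]]), {}

    def deeplift(self, m, cache, ref_cache):
        return m.reshape([int(v) for v in cache["in_shape"]])


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(1.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x):
        return x @ self.params["W"] + self.params["b"], {"x": x}

    def backward(self, dout, cache):
        dW = cache["x"].T @ dout
        db = dout.sum(axis=0)
        return dout @ self.params["W"].T, {"W": dW, "b": db}

    def deeplift(self, m, cache, ref_cache):
        return m @ self.params["W"].T


class Network:
    """A feed-forward stack producing a single logit per example."""

    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, with_caches: bool = False):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        logit = x[:, 0]
        return (logit, caches) if with_caches else logit

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))

    def backward(self, dlogit: np.ndarray, caches) -> List[Dict[str, np.ndarray]]:
        """Gradients of the loss w.r.t. every parameter, given d(loss)/d(logit)."""
        grads: List[Dict[str, np.ndarray]] = [None] * len(self.layers)
        d = dlogit[:, None]
        for i in range(len(self.layers) - 1, -1, -1):
            d, g = self.layers[i].backward(d, caches[i])
            grads[i] = g
        return grads

    def deeplift_multipliers(
        self, m_logit: np.ndarray, caches, ref_caches
    ) -> np.ndarray:
        """Propagate output multipliers back to the input."""
        m = m_logit[:, None]
        for i in range(len(self.layers) - 1, -1, -1):
            m = self.layers[i].deeplift(m, caches[i], ref_caches[i])
        return m

    def get_params(self) -> List[Dict[str, np.ndarray]]:
        return [
            {k: v.copy() for k, v in layer.params.items()}
            for layer in self.layers
        ]

    def set_params(self, params: List[Dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.layers, params):
            for k, v in p.items():
                layer.params[k] = v.copy()


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in network.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in network.layers
        ]

    def step(self, grads: List[Dict[str, np.ndarray]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, g, m, v in zip(self.network.layers, grads, self.m, self.v):
            for k in layer.params:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
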