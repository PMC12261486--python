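"""Minimal feed-forward network core with explicit backpropagation.

The training engine needs per-task gradients over the *shared* trunk
parameters to run gradient surgery, so the forward/backward passes are
spelled out on numpy arrays: an :class:`MLP` is a stack of dense layers
with ReLU between them (linear final layer), and :class:`Adam` is the
optimizer.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "flatten_arrays", "unflatten_like", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def flatten_arrays(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def unflatten_like(flat: np.ndarray, template: list[np.ndarray]) -> list[np.ndarray]:
    out, offset = [], 0
    for a in template:
        out.append(flat[offset : offset + a.size].reshape(a.shape))
        offset += a.size
    if offset != flat.size:
        raise ValueError("flat vector size does not match template")
    return out


class MLP:
    """Dense layers with ReLU activations between them; linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    @property
    def in_dim(self) -> int:
        return self.sizes[0]

    @property
    def out_dim(self) -> int:
        return self.sizes[-1]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (output, cache); cache holds the layer inputs for backward."""
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(
                f"expected input of width {self.in_dim}, got shape {x.shape}"
            )
        cache = []
        h = x
        for layer in range(self.n_layers):
            cache.append(h)
            w, b = self.params[2 * layer], self.params[2 * layer + 1]
            h = h @ w + b
            if layer < self.n_layers - 1:
                h = np.maximum(h, 0.0)
        return h, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(
        self, d_out: np.ndarray, cache: list[np.ndarray]
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Backpropagate d(loss)/d(output); return (param grads, d(input))."""
        grads = [np.zeros_like(p) for p in self.params]
        delta = d_out
        for layer in range(self.n_layers - 1, -1, -1):
            h_in = cache[layer]
            w, b = self.params[2 * layer], self.params[2 * layer + 1]
            if layer < self.n_layers - 1:
                # the cached input of layer+1 is this layer's post-ReLU output
                post = cache[layer + 1] if layer + 1 < len(cache) else None
                if post is None:  # pragma: no cover - cache always full
                    raise RuntimeError("incomplete cache")
                delta = delta * (post > 0)
            grads[2 * layer] = h_in.T @ delta
            grads[2 * layer + 1] = delta.sum(axis=0)
            delta = delta @ w.T
        return grads, delta

    def backward_with_relu(
        self, d_out: np.ndarray, cache: list[np.ndarray]
    ) -> tuple[list[np.ndarray], np.ndarray]:  # pragma: no cover - alias
        return self.backward(d_out, cache)

    def get_flat(self) -> np.ndarray:
        return flatten_arrays(self.params)

    def set_flat(self, flat: np.ndarray) -> None:
        for p, new in zip(self.params, unflatten_like(flat, self.params)):
            p[...] = new

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]


class Adam:
    """Adam over a flat list of parameter arrays, updated in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
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
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
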