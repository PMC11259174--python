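"""Minimal numpy neural-network layers with explicit reverse-mode gradients.

No autodiff framework is available in the deployment environment, so the
layers here implement forward passes that return a context object and
backward passes that consume it, accumulating parameter gradients in-place.
This is sufficient for the feedforward and LSTM-based actor-critic networks
and their BPTT training.

Conventions: inputs are batched row-wise ``(B, n_in)``; parameter init is
fan-in uniform ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = ["Linear", "LSTMCell", "MLP", "Adam", "Network",
           "global_norm_clip", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters and their gradient accumulators live in two dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / math.sqrt(n_in)
        self._register("W", rng.uniform(-k, k, size=(n_in, n_out)))
        self._register("b", rng.uniform(-k, k, size=n_out))

    def forward(self, x: np.ndarray):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, ctx, dy: np.ndarray) -> np.ndarray:
        x = ctx
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class MLP(Layer):
    """Stack of Linear layers with ReLU after every layer (no output head)."""

    def __init__(self, n_in: int, widths: Iterable[int], rng: np.random.Generator):
        super().__init__()
        self.layers: list[Linear] = []
        prev = n_in
        for w in widths:
            self.layers.append(Linear(prev, int(w), rng))
            prev = int(w)
        self.n_out = prev
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                self.params[f"l{i}.{name}"] = p
                self.grads[f"l{i}.{name}"] = layer.grads[name]

    def forward(self, x: np.ndarray):
        ctxs = []
        for layer in self.layers:
            y, lin_ctx = layer.forward(x)
            mask = y > 0
            x = y * mask
            ctxs.append((lin_ctx, mask))
        return x, ctxs

    def backward(self, ctxs, dy: np.ndarray) -> np.ndarray:
        for layer, (lin_ctx, mask) in zip(reversed(self.layers), reversed(ctxs)):
            dy = layer.backward(lin_ctx, dy * mask)
        return dy


class LSTMCell(Layer):
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, n_in: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.n_in = n_in
        self.width = width
        k = 1.0 / math.sqrt(width)
        self._register("W_ih", rng.uniform(-k, k, size=(n_in, 4 * width)))
        self._register("W_hh", rng.uniform(-k, k, size=(width, 4 * width)))
        self._register("b", rng.uniform(-k, k, size=4 * width))

    def forward(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        H = self.width
        z = x @ self.params["W_ih"] + h @ self.params["W_hh"] + self.params["b"]
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        ctx = (x, h, c, i, f, g, o, tc)
        return h_new, c_new, ctx

    def backward(self, ctx, dh: np.ndarray, dc: np.ndarray):
        x, h, c, i, f, g, o, tc = ctx
        dtc = dh * o * (1.0 - tc * tc) + dc
        do = dh * tc
        df = dtc * c
        di = dtc * g
        dg = dtc * i
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        self.grads["W_ih"] += x.T @ dz
        self.grads["W_hh"] += h.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        dx = dz @ self.params["W_ih"].T
        dh_prev = dz @ self.params["W_hh"].T
        dc_prev = dtc * f
        return dx, dh_prev, dc_prev


class Network(Layer):
    """A container aggregating named sub-layers into one parameter namespace."""

    def __init__(self) -> None:
        super().__init__()
        self._children: dict[str, Layer] = {}

    def add(self, name: str, layer: Layer) -> Layer:
        self._children[name] = layer
        for pname, p in layer.params.items():
            self.params[f"{name}.{pname}"] = p
            self.grads[f"{name}.{pname}"] = layer.grads[pname]
        return layer

    def zero_grad(self) -> None:
        for child in self._children.values():
            child.zero_grad()

    # state copying used for target networks and checkpoints
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k][...] = v


def global_norm_clip(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in-place so their global L2 norm <= max_norm."""
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1.5e-4)."""

    def __init__(self, net: Layer, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1.5e-4):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in net.params.items()}
        self.v = {k: np.zeros_like(p) for k, p in net.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.net.params.items():
            g = self.net.grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.lr = state["lr"]
        for k in self.m:
            self.m[k][...] = state["m"][k]
            self.v[k][...] = state["v"][k]
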