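"""Minimal numpy neural-network primitives for the temporal RSD model.

Implements exactly what the recurrent multi-task predictor needs — an LSTM
layer with truncated backpropagation through time, linear heads, weighted
cross-entropy and Smooth L1 losses with analytic gradients, and Adam — in
plain numpy with hand-derived backward passes.  Everything is deterministic
given the initialisation rng.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMLayer",
    "Linear",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
    "smooth_l1",
    "clip_gradients",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTMLayer:
    """Single LSTM layer processed one timestep at a time (batch size 1).

    Gate order in the fused weight matrices is (input, forget, cell, output).
    The input projection for a whole chunk is precomputed in one matmul when
    the full input sequence is known up front.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden = hidden
        s = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s, s, size=(4 * hidden, in_dim))
        self.Wh = rng.uniform(-s, s, size=(4 * hidden, hidden))
        self.b = rng.uniform(-s, s, size=4 * hidden)
        # forget-gate bias offset for stable long-sequence training
        self.b[hidden : 2 * hidden] += 1.0

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.Wx": self.Wx, f"{prefix}.Wh": self.Wh, f"{prefix}.b": self.b}

    def init_state(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(self.hidden), np.zeros(self.hidden)

    def _gates(self, zx: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, ...]:
        H = self.hidden
        z = zx + self.Wh @ h + self.b
        i = _sigmoid(z[:H])
        f = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = _sigmoid(z[3 * H :])
        return i, f, g, o

    def step(
        self, x: np.ndarray, h: np.ndarray, c: np.ndarray, zx: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, tuple]:
        """One timestep; returns (h', c', cache_entry)."""
        if zx is None:
            zx = self.Wx @ x
        i, f, g, o = self._gates(zx, h)
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        return h_new, c_new, (x, h, c, i, f, g, o, c_new, tc)

    def forward_sequence(
        self, X: np.ndarray, h0: np.ndarray, c0: np.ndarray
    ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], list]:
        """Process a (T, in_dim) chunk; returns (H_out, final state, cache)."""
        ZX = X @ self.Wx.T
        h, c = h0, c0
        cache: list[tuple] = []
        H_out = np.empty((len(X), self.hidden))
        for t in range(len(X)):
            h, c, entry = self.step(X[t], h, c, zx=ZX[t])
            cache.append(entry)
            H_out[t] = h
        return H_out, (h, c), cache

    def backward_sequence(
        self, cache: list, dH: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backprop a chunk: returns (param grads, dX).

        Gradients flowing out of the chunk boundary (into the carried-in
        state) are dropped — truncated BPTT.
        """
        T = len(cache)
        H = self.hidden
        DZ = np.empty((T, 4 * H))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = dH[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            DZ[t] = dz
            dh_next = self.Wh.T @ dz
            dc_next = dc * f
        X = np.stack([e[0] for e in cache])
        Hprev = np.stack([e[1] for e in cache])
        grads = {
            "Wx": DZ.T @ X,
            "Wh": DZ.T @ Hprev,
            "b": DZ.sum(axis=0),
        }
        dX = DZ @ self.Wx
        return grads, dX


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-s, s, size=(out_dim, in_dim))
        self.b = rng.uniform(-s, s, size=out_dim)

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def forward(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W.T + self.b

    def backward(self, X: np.ndarray, dY: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        return {"W": dY.T @ X, "b": dY.sum(axis=0)}, dY @ self.W


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy over (T, C) logits.

    Normalised by the summed weights of the realised targets (so unobserved
    classes with weight 0 are excluded from the loss entirely); gradient is
    with respect to the logits.
    """
    T = len(targets)
    probs = softmax(logits, axis=1)
    w = weights[targets]
    wsum = float(w.sum())
    if wsum <= 0.0:
        return 0.0, np.zeros_like(logits)
    logp = np.log(np.clip(probs[np.arange(T), targets], 1e-300, None))
    loss = float(-(w * logp).sum() / wsum)
    dlogits = probs * w[:, None]
    dlogits[np.arange(T), targets] -= w
    dlogits /= wsum
    return loss, dlogits


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float) -> tuple[float, np.ndarray]:
    """Smooth L1 (Huber-style): 0.5 x^2 / beta for |x| < beta, else |x| - beta/2."""
    x = pred - target
    ax = np.abs(x)
    quad = ax < beta
    loss_vec = np.where(quad, 0.5 * x * x / beta, ax - 0.5 * beta)
    dvec = np.where(quad, x / beta, np.sign(x))
    n = max(len(x), 1)
    return float(loss_vec.mean()) if len(x) else 0.0, dvec / n


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


@dataclass
class Adam:
    """Adam over a named parameter dict, updated in place."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for name, p in params.items():
            g = grads.get(name)
            if g is None:
                continue
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
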