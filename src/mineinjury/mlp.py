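"""A small, deterministic multilayer perceptron in numpy.

Two ReLU hidden layers with inverted dropout, Adam optimisation, and a
task-specific output layer: softmax with cross-entropy for classification,
softplus with squared error for regression (so predictions can never be
negative). Single-threaded and fully seeded, so training is reproducible
bit for bit.

Inputs are standardized internally (train-set mean and standard
deviation); for regression the softplus output is multiplied by the
train-set target scale, which keeps the non-negativity guarantee while
letting Adam work on O(1) quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLP:
    task: str  # "classification" | "regression"
    hidden: tuple[int, int] = (128, 64)
    learning_rate: float = 0.001
    dropout: float = 0.3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    # -- helpers --------------------------------------------------------------

    def _forward(self, x, rng=None):
        a1 = x @ self.w1 + self.b1
        h1 = np.maximum(a1, 0.0)
        m1 = None
        if rng is not None and self.dropout > 0:
            m1 = (rng.random(h1.shape) >= self.dropout) / (1.0 - self.dropout)
            h1 = h1 * m1
        a2 = h1 @ self.w2 + self.b2
        h2 = np.maximum(a2, 0.0)
        m2 = None
        if rng is not None and self.dropout > 0:
            m2 = (rng.random(h2.shape) >= self.dropout) / (1.0 - self.dropout)
            h2 = h2 * m2
        z = h2 @ self.w3 + self.b3
        return a1, h1, m1, a2, h2, m2, z

    def fit(self, x: np.ndarray, y: Sequence) -> "MLP":
        x = np.asarray(x, dtype=np.float64)
        rng = np.random.default_rng(self.seed)
        self.x_mean = x.mean(axis=0)
        self.x_std = x.std(axis=0)
        self.x_std[self.x_std == 0] = 1.0
        xs = (x - self.x_mean) / self.x_std
        n, p = xs.shape

        if self.task == "classification":
            y = np.asarray(y)
            self.classes_ = np.array(sorted(set(y.tolist())))
            cindex = {c: i for i, c in enumerate(self.classes_.tolist())}
            yi = np.array([cindex[v] for v in y.tolist()])
            n_out = len(self.classes_)
            self.y_scale = 1.0
        else:
            yv = np.asarray(y, dtype=np.float64).ravel()
            self.y_scale = float(yv.std()) or 1.0
            yt = yv / self.y_scale
            n_out = 1

        h1n, h2n = self.hidden
        def init(fan_in, fan_out):
            return (rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))

        self.w1, self.b1 = init(p, h1n), np.zeros(h1n)
        self.w2, self.b2 = init(h1n, h2n), np.zeros(h2n)
        self.w3, self.b3 = init(h2n, n_out), np.zeros(n_out)

        params = ["w1", "b1", "w2", "b2", "w3", "b3"]
        mom = {k: np.zeros_like(getattr(self, k)) for k in params}
        vel = {k: np.zeros_like(getattr(self, k)) for k in params}
        b1a, b2a, eps = 0.9, 0.999, 1e-8
        t = 0

        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                xb = xs[sel]
                a1, h1, m1, a2, h2, m2, z = self._forward(xb, rng)
                bsz = len(sel)
                if self.task == "classification":
                    probs = softmax(z)
                    dz = probs
                    dz[np.arange(bsz), yi[sel]] -= 1.0
                    dz /= bsz
                else:
                    pred = softplus(z).ravel()
                    sig = 1.0 / (1.0 + np.exp(-z.ravel()))
                    dz = (2.0 * (pred - yt[sel]) * sig / bsz)[:, None]

                grads = {}
                grads["w3"] = h2.T @ dz
                grads["b3"] = dz.sum(axis=0)
                dh2 = dz @ self.w3.T
                if m2 is not None:
                    dh2 = dh2 * m2
                dh2[a2 <= 0] = 0.0
                grads["w2"] = h1.T @ dh2
                grads["b2"] = dh2.sum(axis=0)
                dh1 = dh2 @ self.w2.T
                if m1 is not None:
                    dh1 = dh1 * m1
                dh1[a1 <= 0] = 0.0
                grads["w1"] = xb.T @ dh1
                grads["b1"] = dh1.sum(axis=0)

                t += 1
                for k in params:
                    g = grads[k]
                    mom[k] = b1a * mom[k] + (1 - b1a) * g
                    vel[k] = b2a * vel[k] + (1 - b2a) * g * g
                    mhat = mom[k] / (1 - b1a**t)
                    vhat = vel[k] / (1 - b2a**t)
                    setattr(
                        self,
                        k,
                        getattr(self, k) - self.learning_rate * mhat / (np.sqrt(vhat) + eps),
                    )
        return self

    def _infer(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1] != len(self.x_mean):
            raise ValueError(
                f"feature count mismatch: model expects {len(self.x_mean)}, got {x.shape[1]}"
            )
        xs = (x - self.x_mean) / self.x_std
        *_, z = self._forward(xs, rng=None)
        return z

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is only defined for classification")
        return softmax(self._infer(x))

    def predict(self, x: np.ndarray):
        z = self._infer(x)
        if self.task == "classification":
            return self.classes_[np.argmax(z, axis=1)]
        return softplus(z).ravel() * self.y_scale
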