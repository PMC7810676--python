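"""Minimal feed-forward binary MLP in numpy.

Three ReLU hidden layers, inverted dropout on the last hidden layer,
a single sigmoid output trained with cross-entropy and Adam.  Written
for full determinism under a seed and small-dataset training speed;
float32 throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BinaryMLP:
    """Binary classifier ``d -> h1 -> h2 -> h3 -> 1``.

    Parameters mirror the usual Adam defaults; ``dropout_last`` applies
    inverted dropout to the final hidden layer during training only, so
    inference is deterministic.
    """

    def __init__(
        self,
        n_inputs: int,
        hidden: Sequence[int] = (2000, 1500, 1000),
        dropout_last: float = 0.5,
        learning_rate: float = 1e-3,
        epochs: int = 30,
        batch_size: int = 32,
        seed: int = 0,
    ) -> None:
        self.n_inputs = int(n_inputs)
        self.hidden = tuple(int(h) for h in hidden)
        self.dropout_last = float(dropout_last)
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self._fitted = False

    @property
    def layer_sizes(self) -> tuple:
        return (self.n_inputs, *self.hidden, 1)

    def _init_params(self, rng: np.random.Generator) -> None:
        sizes = self.layer_sizes
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU
            self.W.append(
                (scale * rng.standard_normal((fan_in, fan_out))).astype(np.float32)
            )
            self.b.append(np.zeros(fan_out, dtype=np.float32))

    def _forward(self, X: np.ndarray, rng=None):
        """Returns (activations, pre-dropout last hidden, output probs).

        With ``rng`` given, applies inverted dropout to the last hidden
        layer (training mode)."""
        acts = [X]
        a = X
        n_hidden = len(self.hidden)
        for i in range(n_hidden):
            a = np.maximum(a @ self.W[i] + self.b[i], 0.0)
            if i == n_hidden - 1 and rng is not None and self.dropout_last > 0:
                keep = 1.0 - self.dropout_last
                mask = (rng.random(a.shape) < keep).astype(np.float32) / keep
                a = a * mask
            acts.append(a)
        z_out = a @ self.W[-1] + self.b[-1]
        p = _sigmoid(z_out)
        return acts, p

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryMLP":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(f"expected inputs of width {self.n_inputs}")
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)

        n = X.shape[0]
        n_layers = len(self.W)
        # Adam state
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb, yb = X[idx], y[idx]
                acts, p = self._forward(xb, rng=rng)
                # cross-entropy + sigmoid gives the simple output delta
                delta = (p - yb) / xb.shape[0]
                t += 1
                for i in range(n_layers - 1, -1, -1):
                    gW = acts[i].T @ delta
                    gb = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.W[i].T) * (acts[i] > 0)
                    for g, m, v, param in (
                        (gW, mW[i], vW[i], self.W[i]),
                        (gb, mb[i], vb[i], self.b[i]),
                    ):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        mhat = m / (1 - beta1**t)
                        vhat = v / (1 - beta2**t)
                        param -= (
                            self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                        ).astype(np.float32)
        self._fitted = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("predict called before fit")
        X = np.asarray(X, dtype=np.float32)
        _, p = self._forward(X, rng=None)
        return p.reshape(-1).astype(np.float64)
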