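"""Minimal feed-forward softmax network with hand-written differentiation.

The state-assignment function chi is a multilayer perceptron ending in a
softmax, so its outputs always live on the probability simplex.  Training
maximizes a variational score of the lagged covariances of chi, which is not
a per-sample loss, so the backward pass is written explicitly: the score's
gradient with respect to the batch of network outputs is pushed through the
softmax and the hidden layers.  The same machinery yields exact gradients of
any output probability with respect to the inputs, which downstream modules
use for saliency analysis.

Activations: ``tanh`` (smooth, the default — exact input gradients matter
here) and ``selu`` (the self-normalizing alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "selu":
        return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - a * a
    if kind == "selu":
        return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))
    raise ValueError(f"unknown activation {kind!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MLP:
    """Weights of a fully connected softmax network.

    ``weights[l]`` has shape (d_l, d_{l+1}); the final layer feeds a softmax
    of width M (the number of states).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "tanh"

    @classmethod
    def init(cls, n_in: int, hidden: tuple[int, ...], n_out: int,
             activation: str, rng: np.random.Generator) -> "MLP":
        sizes = [n_in, *hidden, n_out]
        ws, bs = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            # LeCun-normal init keeps self-normalizing nets in regime and is
            # a fine choice for tanh at these widths.
            ws.append(rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b)))
            bs.append(np.zeros(b))
        return cls(ws, bs, activation)

    @property
    def n_in(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_out(self) -> int:
        return self.weights[-1].shape[1]

    def forward(self, x: np.ndarray, cache: bool = False):
        """Return softmax probabilities (B, M); optionally the layer cache."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        acts = [x]
        zs = []
        h = x
        last = len(self.weights) - 1
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            zs.append(z)
            h = softmax(z) if l == last else _act(z, self.activation)
            acts.append(h)
        if cache:
            return acts[-1], (acts, zs)
        return acts[-1]

    def backward(self, cache, d_prob: np.ndarray, *, wrt_input: bool = False):
        """Backpropagate an upstream gradient on the output probabilities.

        Parameters
        ----------
        cache
            Second return of ``forward(..., cache=True)``.
        d_prob
            (B, M) gradient of the objective with respect to the softmax
            output probabilities.
        wrt_input
            If True, also return the (B, n_in) gradient with respect to the
            network input.

        Returns
        -------
        (d_weights, d_biases) summed over the batch, plus d_input if asked.
        """
        acts, zs = cache
        probs = acts[-1]
        # softmax Jacobian: dL/dz_k = p_k (g_k - sum_l g_l p_l)
        delta = probs * (d_prob - np.sum(d_prob * probs, axis=1, keepdims=True))
        dw = [np.empty_like(w) for w in self.weights]
        db = [np.empty_like(b) for b in self.biases]
        for l in range(len(self.weights) - 1, -1, -1):
            dw[l] = acts[l].T @ delta
            db[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.weights[l].T) * _act_grad(
                    zs[l - 1], acts[l], self.activation
                )
            elif wrt_input:
                delta = delta @ self.weights[0].T
        if wrt_input:
            return dw, db, delta
        return dw, db

    def grad_output_wrt_input(self, x: np.ndarray, state: int) -> np.ndarray:
        """Exact gradient d p_state / d x for each row of x; shape (B, n_in)."""
        probs, cache = self.forward(x, cache=True)
        d_prob = np.zeros_like(probs)
        d_prob[:, state] = 1.0
        _, _, dx = self.backward(cache, d_prob, wrt_input=True)
        return dx

    def copy(self) -> "MLP":
        return MLP([w.copy() for w in self.weights],
                   [b.copy() for b in self.biases], self.activation)


class Adam:
    """Adaptive-moment gradient-ascent optimizer over an MLP's parameters."""

    def __init__(self, model: MLP, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        params = model.weights + model.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step_ascent(self, dw: list[np.ndarray], db: list[np.ndarray]) -> None:
        """Move parameters *up* the given gradient (score maximization)."""
        self.t += 1
        grads = dw + db
        params = self.model.weights + self.model.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p += self.lr * mhat / (np.sqrt(vhat) + self.eps)
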