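"""Minimal numpy neural-network primitives shared by the taggers.

Implements exactly what the two sequence models need — parameter
initialisation, a tanh bidirectional RNN with hand-derived
backpropagation-through-time, and Adam — with gradients verified by
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer over a dict of named numpy parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class BiRNN:
    """Single-layer bidirectional tanh RNN, batch size 1.

    Parameters live in an external dict under a ``prefix`` so several
    modules can share one optimizer. Hidden size ``R`` per direction;
    output is the ``L x 2R`` concatenation of both directions.
    """

    def __init__(self, prefix: str, d_in: int, hidden: int):
        self.prefix, self.d_in, self.hidden = prefix, d_in, hidden

    def param_names(self) -> list[str]:
        p = self.prefix
        return [f"{p}.{n}" for n in
                ("Wxf", "Whf", "bf", "Wxb", "Whb", "bb")]

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, R, p = self.d_in, self.hidden, self.prefix
        return {
            f"{p}.Wxf": glorot(rng, d, R), f"{p}.Whf": glorot(rng, R, R),
            f"{p}.bf": np.zeros(R),
            f"{p}.Wxb": glorot(rng, d, R), f"{p}.Whb": glorot(rng, R, R),
            f"{p}.bb": np.zeros(R),
        }

    def forward(self, params: dict, X: np.ndarray):
        """Return (H, cache); H is L x 2R."""
        p = self.prefix
        Wxf, Whf, bf = params[f"{p}.Wxf"], params[f"{p}.Whf"], params[f"{p}.bf"]
        Wxb, Whb, bb = params[f"{p}.Wxb"], params[f"{p}.Whb"], params[f"{p}.bb"]
        L = X.shape[0]
        R = self.hidden
        hf = np.zeros((L, R))
        hb = np.zeros((L, R))
        prev = np.zeros(R)
        for t in range(L):
            prev = np.tanh(X[t] @ Wxf + prev @ Whf + bf)
            hf[t] = prev
        prev = np.zeros(R)
        for t in range(L - 1, -1, -1):
            prev = np.tanh(X[t] @ Wxb + prev @ Whb + bb)
            hb[t] = prev
        return np.concatenate([hf, hb], axis=1), (X, hf, hb)

    def backward(self, params: dict, cache, dH: np.ndarray):
        """Given dLoss/dH, return (grads dict, dLoss/dX)."""
        p = self.prefix
        Wxf, Whf = params[f"{p}.Wxf"], params[f"{p}.Whf"]
        Wxb, Whb = params[f"{p}.Wxb"], params[f"{p}.Whb"]
        X, hf, hb = cache
        L, R = hf.shape
        g = {n: np.zeros_like(params[n]) for n in self.param_names()}
        dX = np.zeros_like(X)
        dhf, dhb = dH[:, :R], dH[:, R:]
        carry = np.zeros(R)
        for t in range(L - 1, -1, -1):
            dpre = (dhf[t] + carry) * (1.0 - hf[t] ** 2)
            hprev = hf[t - 1] if t > 0 else np.zeros(R)
            g[f"{p}.Wxf"] += np.outer(X[t], dpre)
            g[f"{p}.Whf"] += np.outer(hprev, dpre)
            g[f"{p}.bf"] += dpre
            dX[t] += dpre @ Wxf.T
            carry = dpre @ Whf.T
        carry = np.zeros(R)
        for t in range(L):
            dpre = (dhb[t] + carry) * (1.0 - hb[t] ** 2)
            hprev = hb[t + 1] if t < L - 1 else np.zeros(R)
            g[f"{p}.Wxb"] += np.outer(X[t], dpre)
            g[f"{p}.Whb"] += np.outer(hprev, dpre)
            g[f"{p}.bb"] += dpre
            dX[t] += dpre @ Wxb.T
            carry = dpre @ Whb.T
        return g, dX
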