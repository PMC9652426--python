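"""Dense / biLSTM layers and the Adam optimiser on the package's tensor engine.

Time series are handled as lists of per-timestep ``(batch, features)``
tensors; recurrent layers loop over the list so gradients flow through the
whole unrolled sequence.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Dense:
    def __init__(self, rng, n_in, n_out):
        self.W = ad.parameter(glorot(rng, n_in, n_out))
        self.b = ad.parameter(np.zeros(n_out))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class LSTM:
    """A single-direction LSTM; gate order i, f, g, o in one fused matmul."""

    def __init__(self, rng, n_in, hidden):
        self.hidden = hidden
        self.W = ad.parameter(glorot(rng, n_in, 4 * hidden))
        self.U = ad.parameter(glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias, standard initialisation
        self.b = ad.parameter(b)

    def __call__(self, xs):
        H = self.hidden
        B = xs[0].shape[0]
        h = ad.constant(np.zeros((B, H)))
        c = ad.constant(np.zeros((B, H)))
        outs = []
        for x in xs:
            z = x @ self.W + h @ self.U + self.b
            i = ad.sigmoid(z[:, :H])
            f = ad.sigmoid(z[:, H: 2 * H])
            g = ad.tanh(z[:, 2 * H: 3 * H])
            o = ad.sigmoid(z[:, 3 * H: 4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h)
        return outs

    @property
    def params(self):
        return [self.W, self.U, self.b]


class BiLSTM:
    """Forward and backward LSTMs with per-timestep feature concatenation."""

    def __init__(self, rng, n_in, hidden):
        self.fwd = LSTM(rng, n_in, hidden)
        self.bwd = LSTM(rng, n_in, hidden)

    def __call__(self, xs):
        ys_f = self.fwd(xs)
        ys_b = self.bwd(xs[::-1])[::-1]
        return [ad.concat([f, b], axis=1) for f, b in zip(ys_f, ys_b)]

    @property
    def params(self):
        return self.fwd.params + self.bwd.params


class Embedding:
    """Class-embedding matrix consumed through soft lookups.

    A probability block ``p`` of shape (N, K) maps to ``p @ E`` — the
    probability-weighted average of the K embedding rows.  A one-hot block
    reduces exactly to an ordinary row lookup.
    """

    def __init__(self, rng, n_classes, dim):
        self.E = ad.parameter(glorot(rng, n_classes, dim))

    def __call__(self, probs: ad.Tensor) -> ad.Tensor:
        return probs @ self.E

    @property
    def params(self):
        return [self.E]


class Adam:
    """Adam with the beta settings conventional for gradient-penalty critics."""

    def __init__(self, params, lr=1e-3, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, ad.Tensor) else g
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
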