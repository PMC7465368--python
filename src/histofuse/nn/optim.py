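"""First-order optimizers over lists of :class:`~histofuse.nn.layers.Param`.

The six update rules mirror the common Keras definitions so a configuration
written for that framework transfers directly.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    name = "base"

    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = lr
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    name = "SGD"

    def __init__(self, params, lr=1e-2, momentum=0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class RMSprop(Optimizer):
    name = "RMSprop"

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self._s = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self._s):
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adadelta(Optimizer):
    name = "Adadelta"

    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self._s = [np.zeros_like(p.data) for p in self.params]
        self._d = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s, d in zip(self.params, self._s, self._d):
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            upd = np.sqrt(d + self.eps) / np.sqrt(s + self.eps) * p.grad
            p.data -= self.lr * upd
            d *= self.rho
            d += (1 - self.rho) * upd ** 2


class Adam(Optimizer):
    name = "Adam"

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)


class Adamax(Optimizer):
    name = "Adamax"

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1 = self.beta1
        lr_t = self.lr / (1 - b1 ** self.t)
        for p, m, u in zip(self.params, self._m, self._u):
            m *= b1
            m += (1 - b1) * p.grad
            np.maximum(self.beta2 * u, np.abs(p.grad), out=u)
            p.data -= lr_t * m / (u + self.eps)


class Nadam(Adam):
    name = "Nadam"

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** (self.t + 1)) \
                + (1 - b1) * p.grad / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


_OPTIMIZERS = {c.name: c for c in
               (SGD, RMSprop, Adadelta, Adam, Adamax, Nadam)}


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    """Build an optimizer by its (case-insensitive) name."""
    lookup = {k.lower(): v for k, v in _OPTIMIZERS.items()}
    try:
        cls = lookup[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return cls(params, lr=lr)
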