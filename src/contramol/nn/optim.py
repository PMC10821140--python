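"""AdamW (decoupled weight decay) over named parameter dicts."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class AdamW:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self._v = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self.frozen: set[str] = set()

    def freeze(self, names):
        self.frozen.update(names)

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for n, p in self.params.items():
            if p.grad is None or n in self.frozen:
                continue
            m = self._m[n] = self.b1 * self._m[n] + (1 - self.b1) * p.grad
            v = self._v[n] = self.b2 * self._v[n] + (1 - self.b2) * p.grad ** 2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
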