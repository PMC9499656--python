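"""Adam optimizer over lists of numpy parameter arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with optional L2 weight decay added to the gradient.

    Matches the common deep-learning-framework semantics: decay is
    coupled (added to the raw gradient before the moment updates).
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
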