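"""Adam optimizer with decoupled-from-nothing classic L2 weight decay."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["Adam"]


class Adam:
    """Adaptive moment estimation over a list of parameters.

    ``weight_decay`` adds an L2 term to the gradient before the moment
    updates (classic Adam-with-L2 behaviour).
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        scale = self.lr / bc1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            denom = np.sqrt(v / bc2)
            denom += self.eps
            p.data -= scale * m / denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
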