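"""Adam optimizer operating in place on layer parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params_and_grads, lr=0.001, beta1=0.9, beta2=0.999,
                 eps=1e-8, decay=0.0):
        self.slots = list(params_and_grads)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.decay = decay
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name in self.slots]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name in self.slots]

    def step(self):
        self.t += 1
        lr = self.lr / (1.0 + self.decay * (self.t - 1))
        b1, b2 = self.beta1, self.beta2
        correct = lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for i, (obj, name) in enumerate(self.slots):
            p = getattr(obj, name)
            g = getattr(obj, "d" + name)
            self.m[i] += (1.0 - b1) * (g - self.m[i])
            self.v[i] += (1.0 - b2) * (g * g - self.v[i])
            p -= correct * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
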