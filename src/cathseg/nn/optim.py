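"""Adam optimizer over the network's trainable layers."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected moment estimates.

    Only layers whose ``trainable`` flag is set are updated, which is
    how the fine-tuning stage freezes everything outside the selected
    deepest layers.  ``eps`` follows the Keras default.
    """

    def __init__(self, model, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for layer in self.model.parameter_layers():
            if not layer.trainable:
                continue
            for key, param in layer.params.items():
                grad = layer.grads[key].astype(np.float32)
                slot = f"{layer.name}.{key}"
                m = self._m.get(slot)
                if m is None:
                    m = np.zeros_like(param)
                    self._m[slot] = m
                    self._v[slot] = np.zeros_like(param)
                v = self._v[slot]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                param -= lr_t * m / (np.sqrt(v) + self.eps)
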