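"""AMSGrad optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AMSGrad", "ReduceLROnPlateau"]


class AMSGrad:
    """AMSGrad variant of Adam (non-decreasing second-moment estimate).

    Update: m, v as in Adam; vhat = max(vhat, v); step uses vhat with the
    Adam bias-correction folded into the step size.  ``l2`` adds the gradient
    of an ``l2 * sum(w^2)`` penalty on regularizable parameters (convolution
    and dense kernels, not biases or batch-norm parameters).
    """

    def __init__(self, model, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, l2: float = 0.0):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps, self.l2 = beta1, beta2, eps, l2
        self.t = 0
        self._slots = []
        for leaf in model.leaves():
            for name, p in leaf.params.items():
                self._slots.append(
                    (leaf, name, np.zeros_like(p), np.zeros_like(p), np.zeros_like(p))
                )

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for leaf, name, m, v, vhat in self._slots:
            g = leaf.grads[name]
            if self.l2 > 0 and name in leaf.reg_params:
                g = g + 2.0 * self.l2 * leaf.params[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            np.maximum(vhat, v, out=vhat)
            leaf.params[name] -= lr_t * m / (np.sqrt(vhat) + self.eps)

    def penalty(self) -> float:
        """Current L2 penalty value (added to reported losses)."""
        if self.l2 == 0:
            return 0.0
        return self.l2 * sum(
            float(np.sum(leaf.params[n] ** 2))
            for leaf in self.model.leaves()
            for n in leaf.reg_params
        )


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: AMSGrad, factor: float = 0.5, patience: int = 4,
                 min_delta: float = 0.0):
        self.opt = optimizer
        self.factor, self.patience, self.min_delta = factor, patience, min_delta
        self.best = np.inf
        self.wait = 0

    def step(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True if lr was reduced."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.opt.lr *= self.factor
            self.wait = 0
            return True
        return False
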