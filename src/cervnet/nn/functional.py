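"""Loss and activation helpers that live outside the module graph."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "cross_entropy"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean loss
    with respect to the logits (softmax minus one-hot, divided by batch size).
    """
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
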