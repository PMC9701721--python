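"""Softmax and the cross-entropy training loss."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          eps: float = 1e-7):
    """Mean cross-entropy of integer labels under softmax(logits).

    Returns ``(loss, probs, dlogits)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    probs = softmax(logits)
    b = logits.shape[0]
    picked = np.clip(probs[np.arange(b), y], eps, 1.0)
    loss = float(-np.log(picked).mean())
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    return loss, probs, dlogits / b
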