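"""Class-weighted softmax cross-entropy on logits."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                           class_weights: np.ndarray | None = None
                           ) -> tuple[float, np.ndarray]:
    """Mean weighted negative log-likelihood and its gradient w.r.t. logits.

    The per-sample losses are weighted by ``class_weights[target]`` and the
    batch loss is normalised by the sum of the applied weights, so a sample
    of a class with weight 2 contributes exactly twice the gradient of an
    otherwise identical weight-1 sample.  Uniform weights reduce to plain
    cross-entropy.
    """
    n, c = logits.shape
    if class_weights is None:
        w = np.ones(n, dtype=logits.dtype)
    else:
        class_weights = np.asarray(class_weights, dtype=logits.dtype)
        if class_weights.shape != (c,):
            raise ValueError(f"class_weights must have length {c}")
        w = class_weights[targets]
    p = softmax(logits)
    eps = np.finfo(logits.dtype).tiny
    nll = -np.log(p[np.arange(n), targets] + eps)
    w_sum = w.sum()
    loss = float((w * nll).sum() / w_sum)
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits *= (w / w_sum)[:, None]
    return loss, dlogits
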