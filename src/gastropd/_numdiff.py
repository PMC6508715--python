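"""Finite-difference Hessians and covariance extraction shared by the fitters."""

from __future__ import annotations

import numpy as np

__all__ = ["hessian", "covariance_from_neg2ll_hessian"]


def hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``.

    Step per coordinate is ``rel_step * max(1, |x_i|)``.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)

    def fp(shift):
        return f(x + shift)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fp(ei) + fp(-ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fp(ei + ej) - fp(ei - ej) - fp(-ei + ej) + fp(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def covariance_from_neg2ll_hessian(H: np.ndarray) -> np.ndarray | None:
    """Covariance of estimates from the Hessian of -2LL.

    The observed information is ``H / 2``; its inverse is the asymptotic
    covariance.  Near-flat likelihood directions (tiny or slightly negative
    eigenvalues from finite-difference noise) are floored so that they map to
    very large — rather than negative or infinite — variances.
    """
    H = 0.5 * (np.asarray(H) + np.asarray(H).T)
    if not np.all(np.isfinite(H)):
        return None
    vals, vecs = np.linalg.eigh(H / 2.0)
    scale = np.max(np.abs(vals)) if vals.size else 0.0
    if scale <= 0.0:
        return None
    floor = 1e-10 * scale
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T
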