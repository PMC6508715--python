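"""Gaussian copula between ordinal variables with calibrated Spearman correlation.

Linking a given ordinal variable X (e.g. clinical T stage) to a generated
ordinal variable Y (e.g. pathologic ypT stage): X is placed on the latent
normal scale by drawing uniformly within its marginal rank interval, the
latent for Y is ``rho_latent * Z_x + sqrt(1-rho^2) * eps``, and Y is read off
its marginal quantiles.  Because discretisation attenuates rank correlation,
``rho_latent`` is calibrated so that the *midrank Spearman correlation of the
discretised pair* — computable in closed form from the bivariate normal cell
probabilities — hits the requested target.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["bvn_cdf", "discretized_spearman", "calibrate_latent_rho", "copula_draw"]

_CLIP = 8.0  # latent thresholds beyond 8 sd carry negligible probability


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal P(X <= h, Y <= k) via Owen's T function."""
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    if rho >= 1.0 - 1e-12:
        return ndtr(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)
    if abs(rho) < 1e-14:
        return ndtr(h) * ndtr(k)
    # avoid the removable singularity of Owen's formula at h = 0 or k = 0
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    s = math.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * s)
    a2 = (h - rho * k) / (k * s)
    beta = np.where(h * k > 0, 0.0, 0.5)
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2) - beta
    return np.clip(val, 0.0, 1.0)


def _thresholds(probs: np.ndarray) -> np.ndarray:
    cum = np.cumsum(probs)
    cut = ndtri(np.clip(cum[:-1], 1e-15, 1 - 1e-15))
    return np.concatenate(([-np.inf], cut, [np.inf]))


def discretized_spearman(rho_latent: float, px: np.ndarray, py: np.ndarray) -> float:
    """Midrank Spearman correlation of the discretised Gaussian-copula pair."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    tx, ty = _thresholds(px), _thresholds(py)
    H, K = np.meshgrid(tx, ty, indexing="ij")
    C = bvn_cdf(H, K, rho_latent)
    cells = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    cells = np.clip(cells, 0.0, None)
    # mid-distribution grades: u_i = F(x_i-) + p_i / 2
    u = np.cumsum(px) - px / 2.0
    v = np.cumsum(py) - py / 2.0
    eu = float(px @ u)
    ev = float(py @ v)
    var_u = float(px @ u**2) - eu**2
    var_v = float(py @ v**2) - ev**2
    if var_u <= 0 or var_v <= 0:
        return float("nan")
    euv = float(u @ cells @ v)
    return (euv - eu * ev) / math.sqrt(var_u * var_v)


_calibration_cache: dict[tuple, float] = {}


def calibrate_latent_rho(target: float, px, py) -> float:
    """Latent correlation whose discretised Spearman equals ``target``."""
    if not -1.0 < target < 1.0:
        raise ValueError("Spearman target must lie strictly inside (-1, 1)")
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    key = (round(target, 10), px.tobytes(), py.tobytes())
    if key in _calibration_cache:
        return _calibration_cache[key]
    if abs(target) < 1e-12:
        return 0.0
    lo, hi = -0.9999, 0.9999
    f = lambda r: discretized_spearman(r, px, py) - target
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo < 0 < f_hi):
        raise ValueError(
            f"Spearman target {target} is unattainable for these marginals "
            f"(attainable range about [{f_lo + target:.3f}, {f_hi + target:.3f}])"
        )
    rho = float(brentq(f, lo, hi, xtol=1e-6))
    _calibration_cache[key] = rho
    return rho


def copula_draw(
    x_values: np.ndarray,
    x_levels: np.ndarray,
    px: np.ndarray,
    y_levels: np.ndarray,
    py: np.ndarray,
    target_spearman: float | None,
    rng: np.random.Generator,
    latent_rho: float | None = None,
) -> np.ndarray:
    """Draw Y values coupled to the observed X values.

    ``x_values`` take values in ``x_levels`` whose marginal probabilities are
    ``px``; Y has levels ``y_levels`` with marginal ``py``.  ``target_spearman``
    of exactly +/-1 produces the comonotone / antimonotone coupling.
    """
    x_values = np.asarray(x_values)
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    level_index = {v: i for i, v in enumerate(x_levels)}
    xi = np.array([level_index[v] for v in x_values])
    cum_x = np.cumsum(px)
    cum_before = cum_x - px
    u = cum_before[xi] + rng.random(x_values.size) * px[xi]
    cum_y = np.cumsum(py)
    if target_spearman is not None and abs(target_spearman) >= 1.0:
        v = u if target_spearman > 0 else 1.0 - u
    else:
        if latent_rho is None:
            latent_rho = calibrate_latent_rho(float(target_spearman), px, py)
        z = ndtri(np.clip(u, 1e-15, 1 - 1e-15))
        z2 = latent_rho * z + math.sqrt(1.0 - latent_rho**2) * rng.standard_normal(
            x_values.size
        )
        v = ndtr(z2)
    yi = np.clip(np.searchsorted(cum_y, v, side="right"), 0, len(py) - 1)
    return np.asarray(y_levels)[yi]
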