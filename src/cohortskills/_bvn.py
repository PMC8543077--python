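"""Standard bivariate normal rectangle probabilities and derivatives.

CDF via Owen's T function (vectorised, absolute accuracy ~1e-14), plus the
closed-form derivatives used by the polychoric estimating equations:
d/d rho Phi2 = bivariate density (Plackett), d/dh Phi2 = phi(h) * Phi(.|h).
Infinite thresholds are clipped to +/-8.5, where the univariate normal tail
is below 1e-16.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t
from scipy.special import ndtr

_CLIP = 8.5
_RHO_MAX = 0.9995  # open-interval bound for correlation estimates


def _prep(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), -_CLIP, _CLIP)
    # nudge exact zeros so the Owen's T decomposition needs no special cases
    return np.where(x == 0.0, 1e-13, x)


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho."""
    h = _prep(h)
    k = _prep(k)
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-15, 1 - 1e-15)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    beta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    out = (
        0.5 * (ndtr(h) + ndtr(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


def bvn_pdf(h, k, rho):
    """Bivariate normal density = d Phi2(h, k; rho) / d rho (Plackett)."""
    h = _prep(h)
    k = _prep(k)
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-15, 1 - 1e-15)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    om = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / om
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))


def bvn_dcdf_dh(h, k, rho):
    """d Phi2(h, k; rho) / dh = phi(h) Phi((k - rho h)/sqrt(1-rho^2))."""
    h = _prep(h)
    k = _prep(k)
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-15, 1 - 1e-15)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    s = np.sqrt(1.0 - rho * rho)
    return np.exp(-0.5 * h * h) / np.sqrt(2 * np.pi) * ndtr((k - rho * h) / s)


def _double_diff(F: np.ndarray) -> np.ndarray:
    """Rectangle combination over the last two (grid) axes."""
    return F[..., 1:, 1:] - F[..., :-1, 1:] - F[..., 1:, :-1] + F[..., :-1, :-1]


def cell_probabilities(H: np.ndarray, K: np.ndarray, rho) -> np.ndarray:
    """Cell probabilities for boundary grids H (..., a+1) and K (..., b+1).

    Boundaries include the infinite endpoints.  Returns (..., a, b).
    """
    H = np.asarray(H, dtype=float)
    K = np.asarray(K, dtype=float)
    rho = np.asarray(rho, dtype=float)
    F = bvn_cdf(H[..., :, None], K[..., None, :], rho[..., None, None])
    return _double_diff(F)


def cell_dprob_drho(H: np.ndarray, K: np.ndarray, rho) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    K = np.asarray(K, dtype=float)
    rho = np.asarray(rho, dtype=float)
    # density vanishes at infinite boundaries
    D = bvn_pdf(H[..., :, None], K[..., None, :], rho[..., None, None])
    D = np.where(np.isfinite(H[..., :, None]) & np.isfinite(K[..., None, :]), D, 0.0)
    return _double_diff(D)
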