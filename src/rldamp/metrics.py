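"""Reconstruction quality metrics on the 0-255 intensity scale."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import DimensionError

__all__ = ["psnr", "ssim"]


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio, ``10 log10(peak^2 / MSE)`` in dB.

    Identical images are flagged by returning ``inf``.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise DimensionError(f"shape mismatch: {ref.shape} vs {test.shape}")
    mse = np.mean((ref - test) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
    peak: float = 255.0,
) -> float:
    """Mean structural similarity with an 11x11 Gaussian window.

    Local statistics are Gaussian-weighted (sigma 1.5, truncated at radius
    5, i.e. an 11x11 window); constants C1 = (k1 L)^2, C2 = (k2 L)^2 with
    dynamic range L = 255.  The SSIM map is edge-cropped by the window
    radius before averaging.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise DimensionError(f"shape mismatch: {ref.shape} vs {test.shape}")
    c1 = (k1 * peak) ** 2
    c2 = (k2 * peak) ** 2
    filt = lambda a: gaussian_filter(a, sigma=sigma, truncate=truncate)

    mu_x = filt(ref)
    mu_y = filt(test)
    mu_xx = filt(ref * ref)
    mu_yy = filt(test * test)
    mu_xy = filt(ref * test)
    var_x = mu_xx - mu_x * mu_x
    var_y = mu_yy - mu_y * mu_y
    cov = mu_xy - mu_x * mu_y

    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    smap = num / den
    pad = int(truncate * sigma + 0.5)
    if smap.shape[0] > 2 * pad and smap.shape[1] > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(smap.mean())
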