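"""Self-contained synthetic inputs: phantom, textures, sparse signals.

Every experiment and test in the package runs on images generated here, so
no external (copyrighted) test images are required or shipped.  All
generators are seeded-deterministic and produce rasters on the 0-255 scale.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError

__all__ = [
    "make_phantom",
    "make_selfsimilar_image",
    "make_sparse_signal",
    "make_lowrank_matrix",
    "make_wavelet_sparse_image",
]

# modified Shepp-Logan head phantom: (intensity, a, b, x0, y0, phi_deg)
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


def make_phantom(n: int) -> np.ndarray:
    """Shepp-Logan head phantom rendered analytically at n x n, scaled 0-255.

    Piecewise-constant ellipses emulate the smooth-region / sharp-edge
    structure of MR test images.  Left-right near-symmetric up to ellipse
    placement (documented, not asserted).
    """
    if n < 2:
        raise ParameterError(f"side must be >= 2, got {n}")
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    x = coords[None, :]
    y = -coords[:, None]  # row 0 is the top of the head
    img = np.zeros((n, n))
    for val, a, b, x0, y0, phi in _SHEPP_LOGAN:
        t = np.deg2rad(phi)
        xr = (x - x0) * np.cos(t) + (y - y0) * np.sin(t)
        yr = -(x - x0) * np.sin(t) + (y - y0) * np.cos(t)
        img += val * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return np.clip(img, 0.0, 1.0) * 255.0


def make_selfsimilar_image(
    n: int, tile_size: int, jitter: float = 10.0, seed: int = 0
) -> np.ndarray:
    """Tiled random texture with per-tile intensity jitter.

    A single smooth random tile is repeated across the image, so patch
    groups are exactly low-rank at ``jitter = 0`` and *near* low-rank for
    positive jitter (a scalar offset per tile) — the self-repeating-pattern
    premise of nonlocal models, in synthetic form.  The default jitter (std
    10 on a texel of contrast 60, about 17% relative variation) reflects
    that repeated patches in natural images are similar but never exact
    copies.
    """
    if tile_size < 1 or tile_size > n:
        raise ParameterError(f"tile_size {tile_size} invalid for side {n}")
    if jitter < 0:
        raise ParameterError(f"jitter must be >= 0, got {jitter}")
    rng = np.random.default_rng(seed)
    # smooth moderate-contrast texel on a mid-gray level, like fabric/brick
    # textures in natural test images (not a white-spectrum random block)
    tile = gaussian_filter(
        rng.uniform(0.0, 1.0, (tile_size, tile_size)), sigma=max(0.8, tile_size / 6), mode="wrap"
    )
    tile = (tile - tile.min()) / max(np.ptp(tile), 1e-12) * 60.0 + 98.0
    reps = int(np.ceil(n / tile_size))
    img = np.tile(tile, (reps, reps))[:n, :n].astype(float)
    if jitter > 0:
        offsets = rng.normal(0.0, jitter, (reps, reps))
        img = img + np.kron(offsets, np.ones((tile_size, tile_size)))[:n, :n]
    return np.clip(img, 0.0, 255.0)


def make_sparse_signal(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Length-n vector with k nonzero standard-normal entries at seeded positions."""
    if k > n or k < 0:
        raise ParameterError(f"k={k} must lie in [0, n={n}]")
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        x[idx] = rng.standard_normal(k)
    return x


def make_lowrank_matrix(
    M: int, N: int, rank: int, noise_std: float = 0.0, seed: int = 0
) -> np.ndarray:
    """``U V^T + noise`` with exact target rank before noise."""
    if rank > min(M, N) or rank < 0:
        raise ParameterError(f"rank={rank} must lie in [0, min(M,N)={min(M, N)}]")
    rng = np.random.default_rng(seed)
    mat = np.zeros((M, N))
    if rank > 0:
        mat = rng.standard_normal((M, rank)) @ rng.standard_normal((rank, N))
    if noise_std > 0:
        mat = mat + rng.normal(0.0, noise_std, (M, N))
    return mat


def make_wavelet_sparse_image(
    n: int, k: int, seed: int = 0, wavelet: str = "db4"
) -> np.ndarray:
    """Image exactly k-sparse in the periodized orthogonal wavelet basis.

    k detail/approximation coefficients are drawn standard-normal at seeded
    positions, reconstructed, then affinely rescaled into [20, 235] — an
    affine map only rescales coefficients and shifts the coarse band, so
    exact sparsity is preserved (up to the handful of coarse coefficients).
    """
    if k > n * n or k < 1:
        raise ParameterError(f"k={k} must lie in [1, n*n={n * n}]")
    rng = np.random.default_rng(seed)
    zero = pywt.wavedec2(np.zeros((n, n)), wavelet, mode="periodization")
    arr, slices = pywt.coeffs_to_array(zero)
    flat = arr.ravel()
    idx = rng.choice(flat.size, size=k, replace=False)
    flat[idx] = rng.standard_normal(k)
    coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec2")
    img = pywt.waverec2(coeffs, wavelet, mode="periodization")[:n, :n]
    lo, hi = img.min(), img.max()
    scale = 215.0 / max(hi - lo, 1e-12)
    return (img - lo) * scale + 20.0
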