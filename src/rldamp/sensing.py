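"""Partial-Fourier measurement system with variable-density k-space sampling.

The sensing operator ``A`` selects ``m`` rows of the unitary 2-D discrete
Fourier transform, the standard model for compressively sampled MRI.  Masks
are generated low-frequency heavy: a fully sampled central square plus a
random remainder drawn with radially decaying probability, mimicking
variable-density acquisition.

Conventions (fixed and relied upon throughout the package):

* The mask grid is stored *fftshift-style*: the DC coefficient sits at the
  array center ``(rows // 2, cols // 2)``.  Internally the operator converts
  to the corner-origin layout of :func:`numpy.fft.fft2`.
* The DFT is unitary (``norm="ortho"``), so the rows of ``A`` are
  orthonormal — the normalization AMP theory assumes.
* Measurement vectors list sampled coefficients in row-major order over the
  fftshifted grid, making them portable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DimensionError, ParameterError

__all__ = [
    "SamplingMask",
    "FourierOperator",
    "generate_vd_mask",
    "generate_nested_masks",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern (fftshifted layout, center = DC).

    Attributes
    ----------
    sampled : ndarray of bool, shape (rows, cols)
        True where a Fourier coefficient is acquired.
    ratio : float
        Target sampling fraction m/n; ``m == round(ratio * rows * cols)``.
    seed : int
        Seed used to draw the random high-frequency locations.
    """

    sampled: np.ndarray
    ratio: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.sampled.shape

    @property
    def m(self) -> int:
        """Number of acquired coefficients."""
        return int(np.count_nonzero(self.sampled))

    @property
    def n(self) -> int:
        return int(self.sampled.size)

    def save(self, path: str | Path) -> None:
        """Write the mask as a 0/1 text grid plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.sampled.astype(np.uint8), fmt="%d")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"shape": list(self.shape), "ratio": self.ratio, "seed": self.seed})
        )

    @classmethod
    def load(cls, path: str | Path) -> "SamplingMask":
        path = Path(path)
        grid = np.loadtxt(path, dtype=np.uint8).astype(bool)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            ratio, seed = float(meta["ratio"]), int(meta["seed"])
        else:
            ratio, seed = grid.mean(), -1
        return cls(sampled=grid, ratio=ratio, seed=seed)


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """Distance (in samples) of each fftshifted grid location from DC."""
    rows, cols = shape
    rr = np.arange(rows) - rows // 2
    cc = np.arange(cols) - cols // 2
    return np.hypot(rr[:, None], cc[None, :])


def generate_vd_mask(
    shape: tuple[int, int],
    ratio: float,
    center_fraction: float = 0.3,
    decay: float = 3.0,
    seed: int = 0,
    r0: float | None = None,
) -> SamplingMask:
    """Generate a variable-density Fourier sampling mask.

    A central square around DC holding ``center_fraction`` of the coefficient
    budget is fully sampled; the remaining budget is drawn without
    replacement with probability proportional to ``(1 + r/r0) ** (-decay)``
    where ``r`` is radial distance from DC.

    Parameters
    ----------
    shape : (rows, cols)
    ratio : float in (0, 1]
        Sampling fraction m/n; the mask has exactly ``round(ratio * n)``
        True entries.
    center_fraction : float in [0, ratio]
        Share of the budget given to the fully sampled central square.
    decay : float > 0
        Polynomial decay exponent of the sampling density.
    seed : int
    r0 : float, optional
        Radial scale of the density; defaults to ``min(shape) / 16``.
    """
    rows, cols = shape
    n = rows * cols
    if not 0.0 < ratio <= 1.0:
        raise ParameterError(f"sampling ratio must lie in (0, 1], got {ratio}")
    if not 0.0 <= center_fraction <= 1.0:
        raise ParameterError(
            f"center_fraction must lie in [0, 1], got {center_fraction}"
        )
    if decay < 0:
        raise ParameterError(f"decay must be nonnegative, got {decay}")
    budget = int(round(ratio * n))
    if budget < 1:
        raise ParameterError(f"budget {budget} < 1 coefficient for shape {shape}")

    sampled = np.zeros((rows, cols), dtype=bool)
    cr, cc = rows // 2, cols // 2  # DC location in fftshifted layout
    if budget >= n:
        sampled[:] = True
        return SamplingMask(sampled=sampled, ratio=ratio, seed=seed)

    # fully sampled central square: largest odd side with side**2 <= share
    side = int(np.floor(np.sqrt(center_fraction * budget)))
    if side % 2 == 0 and side > 0:
        side -= 1
    if side > 0:
        h = side // 2
        sampled[cr - h : cr + h + 1, cc - h : cc + h + 1] = True
    sampled[cr, cc] = True  # DC always acquired

    remaining = budget - int(sampled.sum())
    if remaining > 0:
        r = _radial_frequency(shape)
        scale = r0 if r0 is not None else min(rows, cols) / 16.0
        prob = (1.0 + r / scale) ** (-decay)
        prob[sampled] = 0.0
        flat = prob.ravel()
        flat = flat / flat.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=remaining, replace=False, p=flat)
        sampled.ravel()[idx] = True

    assert int(sampled.sum()) == budget
    return SamplingMask(sampled=sampled, ratio=ratio, seed=seed)


def generate_nested_masks(
    shape: tuple[int, int],
    ratios: tuple[float, ...],
    decay: float = 3.0,
    seed: int = 0,
    r0: float | None = None,
) -> dict[float, SamplingMask]:
    """Nested variable-density masks: lower ratios are subsets of higher ones.

    Emulates retrospective undersampling of a single acquisition, the
    standard protocol for studying the effect of the sampling ratio: every
    location gets a priority key by weighted sampling without replacement
    (exponential race with weights ``(1 + r/r0)**(-decay)``, DC first) and
    the mask at ratio ``rho`` keeps the ``round(rho * n)`` best keys.
    """
    rows, cols = shape
    n = rows * cols
    for ratio in ratios:
        if not 0.0 < ratio <= 1.0:
            raise ParameterError(f"sampling ratio must lie in (0, 1], got {ratio}")
    if decay < 0:
        raise ParameterError(f"decay must be nonnegative, got {decay}")
    r = _radial_frequency(shape)
    scale = r0 if r0 is not None else min(rows, cols) / 16.0
    weights = (1.0 + r / scale) ** (-decay)
    rng = np.random.default_rng(seed)
    keys = rng.exponential(size=shape) / weights
    keys[rows // 2, cols // 2] = -1.0  # DC always acquired first
    order = np.argsort(keys.ravel(), kind="stable")
    out = {}
    for ratio in sorted(ratios):
        budget = int(round(ratio * n))
        if budget < 1:
            raise ParameterError(f"budget {budget} < 1 coefficient for shape {shape}")
        sampled = np.zeros(n, dtype=bool)
        sampled[order[:budget]] = True
        out[ratio] = SamplingMask(sampled=sampled.reshape(shape), ratio=ratio, seed=seed)
    return out


class FourierOperator:
    """Selection of orthonormal 2-D DFT rows: ``y = A x``, ``A A* = I``.

    ``forward`` maps a real (or complex) raster to the sampled coefficients,
    ``adjoint`` zero-fills and inverse-transforms.  Because the DFT is
    unitary and rows are orthonormal, ``forward(adjoint(y)) == y`` for any
    mask and ``adjoint(forward(x)) == x`` at full sampling.
    """

    def __init__(self, mask: SamplingMask):
        self.mask = mask
        self._flat_idx = np.flatnonzero(mask.sampled.ravel())  # row-major over fftshifted grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def m(self) -> int:
        return self.mask.m

    @property
    def n(self) -> int:
        return self.mask.n

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Unitary 2-D DFT restricted to the sampled locations."""
        if image.shape != self.mask.shape:
            raise DimensionError(
                f"image shape {image.shape} does not match mask shape {self.mask.shape}"
            )
        coeffs = np.fft.fftshift(np.fft.fft2(image, norm="ortho"))
        return coeffs.ravel()[self._flat_idx]

    def adjoint(self, meas: np.ndarray) -> np.ndarray:
        """Zero-filled inverse unitary DFT; the exact adjoint of :meth:`forward`."""
        if meas.shape != (self.m,):
            raise DimensionError(f"measurement length {meas.shape} != ({self.m},)")
        grid = np.zeros(self.n, dtype=complex)
        grid[self._flat_idx] = meas
        grid = grid.reshape(self.mask.shape)
        return np.fft.ifft2(np.fft.ifftshift(grid), norm="ortho")


def add_measurement_noise(meas: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add complex white Gaussian noise of total per-coefficient variance ``sigma**2``.

    Real and imaginary parts each receive variance ``sigma**2 / 2`` so that,
    under the unitary-DFT convention, the image-domain equivalent noise has
    standard deviation ``sigma`` on the 0–255 intensity scale.
    """
    if sigma < 0:
        raise ParameterError(f"noise std must be nonnegative, got {sigma}")
    if sigma == 0:
        return meas.copy()
    rng = np.random.default_rng(seed)
    scale = sigma / np.sqrt(2.0)
    noise = rng.normal(scale=scale, size=meas.shape) + 1j * rng.normal(
        scale=scale, size=meas.shape
    )
    return meas + noise
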