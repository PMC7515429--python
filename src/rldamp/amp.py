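"""The D-AMP outer loop: Onsager-corrected residual update + plug-in denoiser.

Per iteration (starting from ``x = 0``, ``z = y``):

1. estimate the effective noise variance ``sigma2 = ||z||^2 / m`` (maximum
   likelihood under the AMP Gaussianity of the residual);
2. back-project: ``h = x + Re(A* z)`` — the "intermediate noisy image";
3. denoise: ``x <- D(h, sigma2)``;
4. estimate the denoiser divergence at ``h`` by Monte-Carlo probing;
5. residual update with Onsager correction:
   ``z <- y - A x + z * (div / m)``.

The Onsager term keeps the effective noise in ``h`` approximately Gaussian
across iterations, which is what lets a plain Gaussian denoiser drive the
reconstruction.  Intermediates are complex under partial-Fourier sampling;
the denoiser consumes the real part (test images are real), the imaginary
part survives only inside ``z``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .denoisers import DenoiserConfig, lr_amp_denoiser, lsm_image_denoiser, wavelet_denoise
from .exceptions import ConfigurationError, DimensionError, DivergenceError, ParameterError
from .metrics import psnr as _psnr, ssim as _ssim
from .report import ReconstructionReport
from .sensing import FourierOperator

logger = logging.getLogger(__name__)

__all__ = [
    "AMPState",
    "estimate_noise_variance",
    "mc_divergence",
    "residual_update",
    "make_denoiser",
    "run_damp",
    "run_rl_damp",
    "run_lr_amp",
    "METHODS",
]


@dataclass
class AMPState:
    """Solver state: estimate, measurement-domain residual, noise variance."""

    x_t: np.ndarray
    z_t: np.ndarray
    sigma2: float
    t: int

    def __post_init__(self):
        if self.sigma2 < 0 or self.t < 0:
            raise ParameterError("sigma2 and t must be nonnegative")


def estimate_noise_variance(z: np.ndarray, m: int) -> float:
    """ML estimate of the effective noise variance: ``||z||_2^2 / m``."""
    z = np.asarray(z)
    if z.size == 0 or m != z.size:
        raise ParameterError(f"m={m} must equal len(z)={z.size} > 0")
    return float(np.sum(np.abs(z) ** 2) / m)


def mc_divergence(
    denoiser: Callable[[np.ndarray], np.ndarray],
    h: np.ndarray,
    epsilon: float | None = None,
    n_probes: int = 1,
    seed: int = 0,
    fx: np.ndarray | None = None,
    return_samples: bool = False,
    probe: str = "rademacher",
):
    """Monte-Carlo estimate of the denoiser divergence at ``h``.

    Averages ``<b, (D(h + eps b) - D(h)) / eps>`` over i.i.d. unit-variance
    probes ``b`` (Hutchinson's estimator).  Rademacher (+/-1) probes are the
    default: ``||b||^2 = n`` exactly, so linear maps yield their divergence
    exactly for any probe and the variance is lower; Gaussian probes are
    available for statistical checks of the estimator itself.

    Parameters
    ----------
    epsilon : float, optional
        Probe step; defaults to ``max(||h||_inf, 1) * 1e-3``.
    fx : array, optional
        Precomputed ``D(h)``, to avoid one denoiser call.
    return_samples : bool
        Also return the per-probe estimates (for standard-error checks).
    probe : {"rademacher", "gaussian"}
    """
    if n_probes < 1:
        raise ParameterError(f"n_probes must be >= 1, got {n_probes}")
    h = np.asarray(h, dtype=float)
    if epsilon is None:
        epsilon = max(float(np.max(np.abs(h))), 1.0) * 1e-3
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    if fx is None:
        fx = denoiser(h)
    fx = np.asarray(fx)
    if fx.shape != h.shape:
        raise DimensionError(f"denoiser output shape {fx.shape} != input {h.shape}")
    if probe not in ("rademacher", "gaussian"):
        raise ParameterError(f"probe must be 'rademacher' or 'gaussian', got {probe!r}")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_probes)
    for k in range(n_probes):
        if probe == "rademacher":
            b = rng.integers(0, 2, size=h.shape).astype(float) * 2.0 - 1.0
        else:
            b = rng.standard_normal(h.shape)
        fb = denoiser(h + epsilon * b)
        samples[k] = float(np.sum(b * (fb - fx)) / epsilon)
    div = float(samples.mean())
    return (div, samples) if return_samples else div


def residual_update(
    y: np.ndarray,
    op: FourierOperator,
    x_t: np.ndarray,
    z_prev: np.ndarray,
    div: float,
    m: int,
) -> np.ndarray:
    """Onsager-corrected residual: ``z = y - A x + z_prev * (div / m)``."""
    if y.shape != z_prev.shape:
        raise DimensionError(f"y shape {y.shape} != z shape {z_prev.shape}")
    return y - op.forward(x_t) + z_prev * (div / m)


def make_denoiser(
    method: str, config: DenoiserConfig | None = None
) -> Callable[[np.ndarray, float], np.ndarray]:
    """Resolve a method id into a ``D(h, sigma2) -> raster`` callable.

    ``rl-damp``: residual-learning nonlocal denoiser; ``lr-amp``: the same
    pipeline without residual centering (plain weighted SVT);
    ``wavelet-amp``: orthogonal-wavelet soft thresholding.
    """
    config = config or DenoiserConfig()
    if method == "rl-damp":
        cache: dict = {}
        return lambda h, s2, commit=False: lsm_image_denoiser(h, s2, config, cache, commit)
    if method == "lr-amp":
        cache_lr: dict = {}
        return lambda h, s2, commit=False: lr_amp_denoiser(h, s2, config, cache_lr, commit)
    if method in ("wavelet-amp", "wavelet"):
        # classic universal-threshold wavelet denoiser: the simple global
        # sparsity baseline the nonlocal methods are compared against
        return lambda h, s2, commit=False: wavelet_denoise(
            h, float(np.sqrt(max(s2, 0.0))), threshold_scale=1.0
        )
    raise ConfigurationError(f"unknown method {method!r}; use rl-damp, lr-amp or wavelet-amp")


METHODS = ("rl-damp", "lr-amp", "wavelet-amp")


def run_damp(
    y: np.ndarray,
    op: FourierOperator,
    denoiser: str | Callable[[np.ndarray, float], np.ndarray] = "rl-damp",
    T: int = 50,
    seed: int = 0,
    ground_truth: np.ndarray | None = None,
    config: DenoiserConfig | None = None,
    epsilon: float | None = None,
    n_probes: int = 1,
    tol: float | None = None,
    callback: Callable[[AMPState], None] | None = None,
) -> ReconstructionReport:
    """Run D-AMP for ``T`` iterations and return a :class:`ReconstructionReport`.

    Parameters
    ----------
    y : complex measurement vector (length ``op.m``).
    denoiser : method id or callable ``D(h, sigma2) -> raster``.
    T : iteration budget (default 50, no early exit unless ``tol`` is set).
    seed : master seed; per-iteration Monte-Carlo probe seeds are spawned
        from it deterministically.
    ground_truth : optional clean image; enables the PSNR/SSIM traces.
    tol : optional relative-change stopping tolerance (off by default).
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    method = denoiser if isinstance(denoiser, str) else getattr(denoiser, "__name__", "custom")
    D = make_denoiser(denoiser, config) if isinstance(denoiser, str) else denoiser
    m = op.m
    if y.shape != (m,):
        raise DimensionError(f"y shape {y.shape} != ({m},)")

    probe_seeds = np.random.SeedSequence(seed).generate_state(T)
    x = np.zeros(op.shape)
    z = y.astype(complex).copy()
    sigma2_trace: list[float] = []
    psnr_trace: list[float] = []
    ssim_trace: list[float] = []

    for t in range(1, T + 1):
        sigma2 = estimate_noise_variance(z, m)
        h = x + np.real(op.adjoint(z))
        try:
            # stateful denoisers update their cross-iteration weight memory
            # only on this committed call, never on divergence probes
            x_new = D(h, sigma2, commit=True)
        except TypeError:
            x_new = D(h, sigma2)
        if not np.all(np.isfinite(x_new)):
            raise DivergenceError(f"non-finite estimate at iteration {t}", iteration=t)
        div = mc_divergence(
            lambda u: D(u, sigma2),
            h,
            epsilon=epsilon,
            n_probes=n_probes,
            seed=int(probe_seeds[t - 1]),
            fx=x_new,
        )
        z = residual_update(y, op, x_new, z, div, m)
        rel_change = float(np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-30))
        x = x_new

        sigma2_trace.append(sigma2)
        logger.debug(
            "iter %d/%d: sigma_hat=%.3f div/m=%.3f rel_change=%.2e",
            t, T, sigma2**0.5, div / m, rel_change,
        )
        if ground_truth is not None:
            clipped = np.clip(x, 0.0, 255.0)
            psnr_trace.append(_psnr(ground_truth, clipped))
            ssim_trace.append(_ssim(ground_truth, clipped))
        if callback is not None:
            callback(AMPState(x_t=x, z_t=z, sigma2=sigma2, t=t))
        if tol is not None and rel_change < tol:
            break

    cfg_echo = (config or DenoiserConfig()).__dict__ if isinstance(denoiser, str) else {}
    return ReconstructionReport(
        final_image=np.clip(x, 0.0, 255.0),
        sigma2_trace=sigma2_trace,
        psnr_trace=psnr_trace,
        ssim_trace=ssim_trace,
        config={"T": T, "n_probes": n_probes, **cfg_echo},
        seed=seed,
        method=method,
    )


def run_rl_damp(y, op, **kwargs) -> ReconstructionReport:
    """Preset: D-AMP with the residual-learning nonlocal denoiser."""
    return run_damp(y, op, denoiser="rl-damp", **kwargs)


def run_lr_amp(y, op, **kwargs) -> ReconstructionReport:
    """Preset: D-AMP with the plain weighted-SVT (no residual) denoiser."""
    return run_damp(y, op, denoiser="lr-amp", **kwargs)
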