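"""statsmodels-style facade: a model object built from data, fit() -> results.

``CSReconstruction`` packages a measurement vector, its sensing operator and
a solver method; ``fit()`` runs D-AMP and returns a
``ReconstructionResult`` carrying the image, per-iteration diagnostics and a
``summary()`` table.  ``from_image`` simulates the full acquisition
(variable-density mask, partial-Fourier measurement, optional noise) from a
clean image, which is the standard evaluation protocol.
"""

from __future__ import annotations

import numpy as np

from .amp import run_damp
from .denoisers import DenoiserConfig
from .metrics import psnr, ssim
from .report import ReconstructionReport
from .sensing import FourierOperator, SamplingMask, add_measurement_noise, generate_vd_mask

__all__ = ["CSReconstruction", "ReconstructionResult"]


class CSReconstruction:
    """Compressed-sensing reconstruction problem ``y = A x + w``.

    Parameters
    ----------
    y : complex measurement vector.
    operator : the partial-Fourier sensing operator.
    method : "rl-damp" (default), "lr-amp" or "wavelet-amp".
    denoiser_config : nonlocal-denoiser parameters.
    ground_truth : optional clean image enabling PSNR/SSIM traces.
    """

    def __init__(
        self,
        y: np.ndarray,
        operator: FourierOperator,
        method: str = "rl-damp",
        denoiser_config: DenoiserConfig | None = None,
        ground_truth: np.ndarray | None = None,
        noise_std: float = 0.0,
    ):
        self.y = y
        self.operator = operator
        self.method = method
        self.denoiser_config = denoiser_config or DenoiserConfig()
        self.ground_truth = ground_truth
        self.noise_std = noise_std

    @classmethod
    def from_image(
        cls,
        image: np.ndarray,
        ratio: float,
        noise_std: float = 0.0,
        seed: int = 0,
        method: str = "rl-damp",
        mask: SamplingMask | None = None,
        denoiser_config: DenoiserConfig | None = None,
        center_fraction: float = 0.3,
        decay: float = 3.0,
    ) -> "CSReconstruction":
        """Simulate acquisition of ``image`` and return the model.

        The mask seed and the measurement-noise seed are spawned
        deterministically from ``seed``.
        """
        image = np.asarray(image, dtype=float)
        sub = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
        if mask is None:
            mask = generate_vd_mask(
                image.shape, ratio, center_fraction=center_fraction, decay=decay,
                seed=int(sub[0]),
            )
        op = FourierOperator(mask)
        y = op.forward(image)
        if noise_std > 0:
            y = add_measurement_noise(y, noise_std, seed=int(sub[1]))
        return cls(
            y, op, method=method, denoiser_config=denoiser_config,
            ground_truth=image, noise_std=noise_std,
        )

    def fit(
        self,
        iterations: int = 50,
        seed: int = 0,
        n_probes: int = 1,
        tol: float | None = None,
    ) -> "ReconstructionResult":
        """Run the solver and return a results object."""
        report = run_damp(
            self.y,
            self.operator,
            denoiser=self.method,
            T=iterations,
            seed=seed,
            ground_truth=self.ground_truth,
            config=self.denoiser_config,
            n_probes=n_probes,
            tol=tol,
        )
        return ReconstructionResult(self, report)


class ReconstructionResult:
    """Results of a D-AMP fit: image, traces, and a summary table."""

    def __init__(self, model: CSReconstruction, report: ReconstructionReport):
        self.model = model
        self.report = report

    @property
    def image(self) -> np.ndarray:
        return self.report.final_image

    @property
    def psnr_trace(self) -> list[float]:
        return self.report.psnr_trace

    @property
    def ssim_trace(self) -> list[float]:
        return self.report.ssim_trace

    @property
    def sigma2_trace(self) -> list[float]:
        return self.report.sigma2_trace

    @property
    def final_psnr(self) -> float:
        return self.report.final_psnr

    @property
    def final_ssim(self) -> float:
        return self.report.final_ssim

    @property
    def iterations(self) -> int:
        return self.report.iterations

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statsmodels results table."""
        op = self.model.operator
        lines = [
            "Compressed-Sensing Reconstruction Results",
            "=" * 45,
            f"{'Method:':<24}{self.report.method}",
            f"{'Image size:':<24}{op.shape[0]} x {op.shape[1]}",
            f"{'Measurements m:':<24}{op.m}",
            f"{'Sampling ratio m/n:':<24}{op.m / op.n:.4f}",
            f"{'Measurement noise std:':<24}{self.model.noise_std:g}",
            f"{'Iterations:':<24}{self.iterations}",
            f"{'Final sigma2:':<24}{self.sigma2_trace[-1]:.6g}",
        ]
        if self.psnr_trace:
            lines.append(f"{'Final PSNR (dB):':<24}{self.final_psnr:.2f}")
            lines.append(f"{'Final SSIM:':<24}{self.final_ssim:.4f}")
        lines.append("=" * 45)
        return "\n".join(lines)

    def evaluate(self, reference: np.ndarray) -> dict[str, float]:
        """PSNR/SSIM of the final image against an arbitrary reference."""
        return {
            "psnr": psnr(reference, self.image),
            "ssim": ssim(reference, self.image),
        }

    def plot_trace(self, ax=None):
        """PSNR-vs-iteration line chart (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.psnr_trace:
            ax.plot(range(1, self.iterations + 1), self.psnr_trace, marker="o", ms=3)
            ax.set_ylabel("PSNR (dB)")
        else:
            ax.plot(range(1, self.iterations + 1), self.sigma2_trace, marker="o", ms=3)
            ax.set_ylabel("estimated sigma^2")
        ax.set_xlabel("iteration")
        ax.set_title(f"{self.report.method} convergence")
        return ax
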