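"""Reconstruction report: final image plus per-iteration diagnostics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ReconstructionReport:
    """Output of a solver run.

    ``psnr_trace`` / ``ssim_trace`` are populated only when a ground-truth
    image was supplied; identical images are flagged with ``inf`` PSNR.
    Trace lengths always equal the number of iterations run.
    """

    final_image: np.ndarray
    sigma2_trace: list[float]
    psnr_trace: list[float] = field(default_factory=list)
    ssim_trace: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    method: str = ""

    @property
    def iterations(self) -> int:
        return len(self.sigma2_trace)

    @property
    def final_psnr(self) -> float:
        return self.psnr_trace[-1] if self.psnr_trace else float("nan")

    @property
    def final_ssim(self) -> float:
        return self.ssim_trace[-1] if self.ssim_trace else float("nan")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "iterations": self.iterations,
            "sigma2_trace": [float(v) for v in self.sigma2_trace],
            "psnr_trace": [float(v) for v in self.psnr_trace],
            "ssim_trace": [float(v) for v in self.ssim_trace],
            "config": self.config,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
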