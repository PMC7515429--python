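# rldamp

Compressed-sensing image recovery by denoising-based approximate message
passing (D-AMP) with a **nonlocal residual-learning denoiser**: groups of
mutually similar patches are centered on a guide estimate, and the singular-
value-domain coefficients of the *residual* are shrunk with adaptive weights
derived from a Laplacian-scale-mixture (LSM) prior.

## The problem

Undersampled Fourier imaging (the CS-MRI acquisition model) measures

```
y = A x + w,        A = S F,   m = |S| < n
```

where `F` is the unitary 2-D DFT, `S` selects a variable-density random
subset of coefficients (dense at low spatial frequencies) and `w` is complex
white Gaussian noise. Recovering `x` requires a prior; nonlocal low-rank
models exploit the fact that stacks of similar patches form near-low-rank
matrices, but pure low-rank shrinkage over-smooths fine texture. Residual
learning instead shrinks only the *difference* between the noisy patch group
`H` and a guide group `B`, preserving detail the guide missed.

## The method

D-AMP iterates, from `x⁰ = 0`, `z⁰ = y`:

```
σ̂²  = ‖zᵗ‖² / m                                  (effective noise, ML estimate)
hᵗ  = xᵗ + Re(A* zᵗ)                             (back-projection)
xᵗ⁺¹ = D(hᵗ; σ̂²)                                 (nonlocal residual denoiser)
zᵗ⁺¹ = y − A xᵗ⁺¹ + zᵗ · div D(hᵗ)/m             (Onsager-corrected residual)
```

The Onsager term (divergence estimated by Monte-Carlo probing) keeps the
effective noise in `hᵗ` approximately Gaussian, which is what licenses a
plain Gaussian denoiser inside the loop.

The denoiser `D`: for each exemplar patch (stride 5), the 36 most similar
6×6 patches are block-matched on a guide image and stacked into `H` (noisy)
and `B` (guide). With `R = H − B = U Σ Vᵀ`, the PCA-domain coefficients
`C = Uᵀ R` are soft-thresholded elementwise at `σ̂² τ`, where

```
τ = (α + 1) / (β + |c|),        α = 0, β = 0.01 (unit intensity scale)
```

is the posterior mean of a Gamma(α, β) hyperprior on the Laplacian inverse
scale of each coefficient — one EM sweep per outer iteration (E-step: the
weights; M-step: the shrinkage). The denoised groups `B + U Ĉ` are
overlap-averaged back into the image. Setting `B = 0` gives the plain
weighted-shrinkage ablation (`lr-amp`); an orthogonal-wavelet soft-threshold
denoiser (`wavelet-amp`) is the global-sparsity baseline.

## Worked example

```python
from rldamp import CSReconstruction
from rldamp.fixtures import make_phantom

image = make_phantom(128)                       # 128x128 head phantom, 0-255
model = CSReconstruction.from_image(image, ratio=0.2, seed=7)   # 20% k-space
result = model.fit(iterations=20, seed=7)
print(result.summary())
```

prints

```
Compressed-Sensing Reconstruction Results
=============================================
Method:                 rl-damp
Image size:             128 x 128
Measurements m:         3277
Sampling ratio m/n:     0.2000
Measurement noise std:  0
Iterations:             20
Final sigma2:           758.464
Final PSNR (dB):        33.68
Final SSIM:             0.9422
=============================================
```

The reconstruction recovers the phantom from 20% of its Fourier
coefficients at 33.7 dB; the same run with `method="lr-amp"` (no residual
learning) reaches 33.0 dB and `method="wavelet-amp"` 15.9 dB, which is the
ordering the residual-learning strategy is designed to produce. A
command-line interface mirrors the library
(`rldamp reconstruct --input img.png --ratio 0.2 --method rl-damp ...`,
plus `mask`, `fixtures`, `measure`, `evaluate` and `grid` subcommands).

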