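# Methods

This note documents the model, the numerical choices and their rationale,
what the synthetic data does and does not emulate, and known limitations.

## Measurement model

`y = A x + w` with `A` a selection of `m` rows of the *unitary* 2-D DFT
(`norm="ortho"`), so the rows of `A` are orthonormal — the normalization
under which AMP's effective-noise bookkeeping is consistent and
`forward∘adjoint` is the identity on measurements. Masks are fftshifted
(DC at the array center) and scanned row-major, making measurement vectors
portable. Variable-density masks fully sample a central square holding 30%
of the coefficient budget and draw the remainder without replacement with
probability ∝ `(1 + r/r₀)^(−decay)`, `decay = 3`, `r₀ = min(shape)/16` —
the paper-standard CS-MRI acquisition shape. `decay = 0` gives the uniform
random ensemble used by the sparse-recovery sanity experiment, where
variable density would leave fine-scale coefficients barely sensed and
their slow convergence would dominate a short iteration budget.

For ratio sweeps a *nested* mask family is provided (priority sampling: an
exponential race keyed by the variable-density weights orders all
locations once; the mask at ratio ρ keeps the first `round(ρ·n)`), which
emulates retrospective undersampling of a single acquisition — along such
a sweep the information content is strictly increasing, so ratio trends
are not confounded by independent mask draws, whose variance at low ratios
is several dB.

Measurement noise of standard deviation σ (quoted on the 0–255 image scale)
is complex Gaussian with variance σ²/2 per real component, so the
image-domain equivalent noise has standard deviation σ under the unitary
convention.

## The residual-learning denoiser

For each exemplar (stride 5 over the pixel grid, last row/column always
included so every pixel is covered) the 36 most similar 6×6 patches inside
a 31-pixel search window are selected by Euclidean block matching, ties
broken by row-major scan order. Matching runs on the *guide* image; the
same coordinates cut the noisy group `H` and guide group `B` (both
`36 × 36`, so the SVD dictionary is square).

Let `R = H − B = U Σ Vᵀ`. Two shrinkage domains are implemented:

* **coefficient** (default): the PCA-domain coefficient matrix `C = Uᵀ R`
  is soft-thresholded elementwise at `σ̂² τ(c)`;
* **spectrum**: the singular values themselves are soft-thresholded at
  `σ̂² τ(s)` — the weighted nuclear-norm proximal family. With constant
  weights this is exactly singular-value thresholding, which the test suite
  verifies against an independent smooth minimizer of
  `‖H − L‖²_F + λ‖L‖_*` (Burer–Monteiro factored form, L-BFGS multistart).

The coefficient domain is the operative default because the hyperparameters
below calibrate shrinkage to the *per-coefficient* noise level σ̂ (each
coefficient of an orthonormal transform carries noise of standard deviation
σ̂ exactly), whereas noise singular values of a 36-column group concentrate
near `2σ̂√M ≈ 12σ̂`; spectrum-domain weights of the same form barely touch
them, leaving a near-identity denoiser whose divergence ≈ n makes the
Onsager gain `div/m > 1` and the outer iteration divergent. The spectrum
domain remains available (and oracle-tested) as the proximal-operator
machinery.

### LSM weights

Each coefficient is modeled as Laplacian with a random inverse scale γ
carrying a Gamma(α, β) hyperprior. Conjugacy gives the posterior
Gamma(α+1, β+|c|), whose mean `(α+1)/(β+|c|)` is the E-step weight; the
M-step is the elementwise soft threshold `max(|c| − σ̂²τ, 0)` (verified
against a dense-grid argmin of the scalar proximal problem). Defaults
α = 0, β = 0.01 — quoted for *unit-scale* intensities, so the pipeline
normalizes coefficients and σ̂² by `intensity_scale = 255` before the
E-step (the cap τ ≤ 1/β is meaningful only on that scale; applied raw on
0–255 data it produces absurd 100σ̂² thresholds). One EM sweep per outer
iteration; `inner_em_iters` and `tau_from_previous` (weights from the
previous iteration's shrunken spectrum) expose the alternative schedules,
but the previous-iterate variant destabilizes under per-iteration group
reshuffling and is off by default.

### The guide

The guide is a pluggable Gaussian denoiser (`bm3d` if that optional package
is installed, `wavelet`, `identity`, or any registered callable). The
default, `nonlocal`, is the package's own no-residual nonlocal pass run
with *guide-grade* settings — α = 2 and two EM sweeps, which makes the
kill/keep decision near-hard and trades a little texture for much lower
noise, the slightly-oversmoothed character wanted of a guide. Inside the
guide, block matching runs on the noisy image itself, as in BM3D's first
stage: patch distances then carry an approximately uniform noise offset
that barely perturbs the ranking, whereas matching on a thresholded
pre-estimate destroys the micro-structure that matching needs (measured:
guide MSE 106 → 76 when switching, vs 45 with oracle matching). Guide-grade
α and sweep count were selected by the guide's own denoising error at fixed
σ on development images. Since the full-image guide is group-independent it
is computed once per denoiser call, not per group.

The ablation method `lr-amp` runs the identical pipeline with `B = 0`
(plain adaptive-weight shrinkage of the noisy groups), so the comparison
isolates residual centering exactly. `wavelet-amp` is the global-sparsity
baseline: soft thresholding of periodized `db4` coefficients at the
universal threshold `σ̂√(2 log n)`. The standalone `wavelet_denoise`
defaults to BayesShrink per-subband thresholds (`σ̂²/σ_x`), which is the
better standalone denoiser; the AMP baseline keeps the universal threshold
deliberately, as the classic simple-prior reference point.

## The outer loop

Canonical D-AMP ordering per iteration: estimate `σ̂² = ‖z‖²/m`;
back-project `h = x + Re(A*z)` (images are real; the imaginary part
survives only inside `z`); denoise; estimate the denoiser divergence at `h`
by Monte-Carlo probing; update the residual with the Onsager correction
`z·div/m`. Probes are i.i.d. Rademacher (Hutchinson's estimator — exact
for linear maps, lower variance than Gaussian probes), one probe per
iteration by default, step `ε = max(‖h‖∞, 1)·10⁻³`. Probe seeds are
spawned per-iteration from the master seed, so runs are bitwise
reproducible. Stateful denoisers update their cross-iteration weight memory
only on the committed call, never on probe calls. Iteration budget is a
fixed `T` (default 50; an optional relative-change tolerance is off by
default). The final image is clipped to [0, 255]; intermediates are not.

Note one boundary effect of the σ̂ estimator: at full sampling the first
residual `z⁰ = y` measures the *signal*, not noise, so the first denoiser
call sees a large σ̂ even though `h = A*y` is already exact; the solver
therefore does not collapse to the identity at ratio 1. The per-pixel
image-domain conversion `σ̂²·m/n` was tested as an alternative and makes
the loop diverge (the denoiser under-thresholds and the Onsager term
amplifies); the measurement-domain estimate is kept.

## Synthetic data

* **Phantom** — the standard head-phantom ellipse composition rendered
  analytically at native resolution (crisp edges, piecewise-constant
  regions): the MR-like test case.
* **Self-similar texture** — one smooth moderate-contrast texel (range
  ≈ [98, 158]) tiled across the image with per-tile intensity jitter
  (std 10, ≈ 17% of texel contrast), since repeated patches in natural
  images are similar but never exact copies. At `jitter = 0` groups are
  exactly low-rank, which the block-matching tests exploit.
* **Wavelet-sparse images** — exactly k-sparse in the periodized `db4`
  basis (affine rescale to [20, 235] preserves the support up to the coarse
  band), for the classic AMP sparse-recovery run.
* **Sparse signals / low-rank matrices** — direct constructions for unit
  tests.

What passing tests on these fixtures show: the operator algebra is exact,
the shrinkage operators equal their proximal definitions, the solver
converges on piecewise-smooth and self-similar content, and residual
learning beats its no-residual ablation under the stated conditions. What
they do not show: performance on natural photographs or real k-space data
(oblique textures, spatially varying noise, phase), or any absolute PSNR
comparable to published numbers on standard test images, which depend on an
unspecified mask law and copyrighted images not shipped here.

## Evaluation protocol and problem sizes

Comparative experiments (the three-method ablation and the noise sweep
0/8/15) run at 128×128, sampling ratio 0.2, T = 20 — the point where this
solver family has reached its comparative ordering — with every method
seeing the same mask and probe seeds, each cell averaged over five seeded
repetitions: final-iterate PSNR fluctuates by roughly ±1 dB on textured
content, and the five-repeat mean is the package's reporting protocol for
comparisons (the noise sweep reuses the ablation's repeat seeds, so the
shared noiseless cell is not rerun). The ratio sweep 0.1/0.2/0.3 instead
runs nested masks to the full termination budget T = 50 with three
repeats: higher ratios pass through a transient oscillation around
iteration 20, the ratio trend is a statement about converged
reconstructions, and margins at convergence are several dB. The
sparse-recovery sanity run
uses a 64×64 image, k = 200, ratio 0.4, uniform mask, T = 30. PSNR uses
peak 255; SSIM is the 11×11 Gaussian-window variant (σ = 1.5, K₁ = 0.01,
K₂ = 0.03, L = 255), cross-checked against scikit-image to 1e-6.

## Known limitations

* Final-iterate oscillation on strongly textured content (hence the
  averaging protocol); residual damping was tried and rejected (it lowers
  absolute quality within the same budget).
* The guide costs one extra nonlocal pass per denoiser call; RL-DAMP is
  roughly twice the price of the ablation per iteration.
* Exemplar stride 5 with 6×6 patches leaves single-pixel coverage at some
  borders; aggregation guards against uncovered pixels but border patches
  get less averaging.
* Grayscale, single-coil, Cartesian-grid Fourier sampling only.
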