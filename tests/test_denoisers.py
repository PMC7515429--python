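"""LSM weights, singular-value shrinkage, group and image denoisers."""

import numpy as np
import pytest
from scipy.integrate import quad

from rldamp import (
    LSMHyperParams,
    denoise_group,
    gamma_posterior_expectation,
    guide_estimate,
    lr_amp_denoiser,
    lsm_image_denoiser,
    shrink_spectrum,
)
from rldamp.denoisers import DenoiserConfig, denoise_group_coef, wavelet_denoise
from rldamp.exceptions import ConfigurationError, DataError, DimensionError, ParameterError
from rldamp import fixtures as fx


def quadrature_posterior_mean(alpha, beta, s):
    """Independent oracle: numerical posterior mean of the Gamma scale.

    The conjugate posterior density is proportional to
    gamma^alpha * exp(-(beta+|s|) gamma); its mean is computed by quadrature
    without using the closed form.
    """
    rate = beta + abs(s)
    num = quad(lambda g: g ** (alpha + 1) * np.exp(-rate * g), 0, np.inf)[0]
    den = quad(lambda g: g**alpha * np.exp(-rate * g), 0, np.inf)[0]
    return num / den


class TestGammaPosterior:
    def test_zero_singular_value(self):
        hyper = LSMHyperParams(alpha=0.0, beta=0.01)
        assert gamma_posterior_expectation(np.array([0.0]), hyper)[0] == pytest.approx(100.0)

    def test_near_unit_singular_value(self):
        hyper = LSMHyperParams(alpha=0.0, beta=0.01)
        assert gamma_posterior_expectation(np.array([0.99]), hyper)[0] == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(30):
            alpha = rng.uniform(0.0, 5.0)
            beta = rng.uniform(1e-3, 2.0)
            s = rng.uniform(0.0, 10.0)
            tau = gamma_posterior_expectation(np.array([s]), LSMHyperParams(alpha, beta))[0]
            assert tau == pytest.approx(quadrature_posterior_mean(alpha, beta, s), abs=1e-8)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ParameterError):
            LSMHyperParams(alpha=-1.0)
        with pytest.raises(ParameterError):
            LSMHyperParams(beta=0.0)


class TestShrinkSpectrum:
    def test_zero_weights_identity(self):
        s = np.array([5.0, 3.0, 1.0])
        assert np.array_equal(shrink_spectrum(s, np.zeros(3), 10.0), s)

    def test_full_shrinkage_to_zero(self):
        s = np.array([1.0, 0.5])
        out = shrink_spectrum(s, np.array([10.0, 10.0]), 1.0)
        assert np.array_equal(out, np.zeros(2))

    def test_scalar_case_matches_grid_argmin(self, rng):
        # 1-D proximal oracle: argmin_u (u-s)^2/(2 sig2) + tau*u over a grid
        for _ in range(50):
            s = rng.uniform(0, 5)
            tau = rng.uniform(0, 3)
            sig2 = rng.uniform(0.1, 2)
            grid = np.arange(0.0, 10.0, 1e-4)
            oracle = grid[np.argmin((grid - s) ** 2 / (2 * sig2) + tau * grid)]
            ours = shrink_spectrum(np.array([s]), np.array([tau]), sig2)[0]
            assert abs(ours - oracle) <= 1e-4 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            shrink_spectrum(np.ones(3), np.ones(2), 1.0)


class TestDenoiseGroup:
    def test_equal_inputs_return_guide(self, rng):
        H = rng.normal(size=(9, 4))
        assert np.array_equal(denoise_group(H, H, 1.0), H)

    def test_rank_one_residual_closed_form(self, rng):
        hyper = LSMHyperParams(alpha=0.0, beta=0.01)
        u = rng.normal(size=6)
        u /= np.linalg.norm(u)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        s, sig2 = 50.0, 1.0
        B = rng.normal(size=(6, 6))
        H = B + s * np.outer(u, v)
        expect = B + (s - sig2 * 1.0 / (0.01 + s)) * np.outer(u, v)
        out = denoise_group(H, B, sig2, hyper)
        assert np.abs(out - expect).max() < 1e-8

    def test_constant_weight_equals_svt_closed_form(self, rng):
        # nuclear-norm prox: SVD + soft threshold at lam/2, computed directly
        for _ in range(100):
            H = rng.normal(size=(5, 5))
            lam = rng.uniform(0.1, 2.0)
            sig2 = 1.0
            U, s, Vt = np.linalg.svd(H)
            svt = (U * np.maximum(s - lam / 2, 0)) @ Vt
            ours = denoise_group(H, np.zeros_like(H), sig2, tau=np.full(5, lam / 2))
            assert np.abs(ours - svt).max() < 1e-8

    def test_nonexpansive_about_guide(self, rng):
        for _ in range(20):
            H = rng.normal(size=(8, 6))
            B = rng.normal(size=(8, 6))
            out = denoise_group(H, B, rng.uniform(0.1, 5.0))
            assert np.linalg.norm(out - B) <= np.linalg.norm(H - B) + 1e-10

    def test_coefficient_variant_nonexpansive_and_guide_fixed(self, rng):
        H = rng.normal(size=(8, 6))
        B = rng.normal(size=(8, 6))
        out = denoise_group_coef(H, B, 2.0)
        assert np.linalg.norm(out - B) <= np.linalg.norm(H - B) + 1e-10
        assert np.array_equal(denoise_group_coef(B, B, 2.0), B)

    def test_beta_to_infinity_returns_noisy(self, rng):
        # guide-faithfulness limit: tau -> 0, no shrinkage
        H = rng.normal(size=(6, 6))
        B = rng.normal(size=(6, 6))
        out = denoise_group(H, B, 1.0, LSMHyperParams(alpha=0.0, beta=1e12))
        assert np.abs(out - H).max() < 1e-6

    def test_sigma2_to_infinity_returns_guide(self, rng):
        H = rng.normal(size=(6, 6))
        B = rng.normal(size=(6, 6))
        out = denoise_group(H, B, 1e12, tau=np.ones(6))
        assert np.abs(out - B).max() < 1e-6

    def test_nonfinite_input_rejected(self):
        H = np.full((4, 4), np.nan)
        with pytest.raises(DataError):
            denoise_group(H, np.zeros((4, 4)), 1.0)


class TestGuideEstimate:
    def test_zero_sigma_returns_input(self, rng):
        img = rng.normal(size=(32, 32))
        for guide in ("wavelet", "identity"):
            assert np.array_equal(guide_estimate(img, 0.0, guide), img)
        # the nonlocal guide aggregates unmodified patches: identity to fp error
        assert np.abs(guide_estimate(img, 0.0, "nonlocal") - img).max() < 1e-10

    def test_wavelet_guide_reduces_noise(self, phantom64, rng):
        noisy = phantom64 + rng.normal(0, 25, phantom64.shape)
        guide = guide_estimate(noisy, 25.0, "wavelet")
        assert np.mean((guide - phantom64) ** 2) < np.mean((noisy - phantom64) ** 2)

    def test_plugins_share_calling_contract(self, rng):
        noisy = rng.uniform(0, 255, (16, 16))
        for guide in ("wavelet", "identity"):
            out = guide_estimate(noisy, 10.0, guide)
            assert out.shape == noisy.shape and np.all(np.isfinite(out))

    def test_unknown_plugin_rejected(self):
        with pytest.raises(ConfigurationError):
            guide_estimate(np.zeros((8, 8)), 1.0, "no-such-denoiser")


class TestImageDenoisers:
    def test_clean_input_zero_sigma_unchanged(self, texture64):
        cfg = DenoiserConfig(guide="wavelet")
        out = lsm_image_denoiser(texture64, 0.0, cfg)
        assert np.abs(out - texture64).max() < 1e-8

    def test_denoising_reduces_mse_on_selfsimilar_image(self, texture64, rng):
        noisy = texture64 + rng.normal(0, 20, texture64.shape)
        out = lsm_image_denoiser(noisy, 400.0)
        assert np.mean((out - texture64) ** 2) < np.mean((noisy - texture64) ** 2)

    def test_residual_learning_not_worse_than_plain_svt(self, texture64, rng):
        noisy = texture64 + rng.normal(0, 20, texture64.shape)
        mse_rl = np.mean((lsm_image_denoiser(noisy, 400.0) - texture64) ** 2)
        mse_lr = np.mean((lr_amp_denoiser(noisy, 400.0) - texture64) ** 2)
        assert mse_rl <= mse_lr

    def test_lr_amp_zero_image_stays_zero(self):
        out = lr_amp_denoiser(np.zeros((32, 32)), 4.0)
        assert np.abs(out).max() < 1e-10

    def test_lr_amp_preserves_constant_image(self):
        # constant groups are rank-1 with one large singular value that
        # survives shrinkage almost untouched
        img = np.full((32, 32), 120.0)
        out = lr_amp_denoiser(img, 4.0, DenoiserConfig(guide="identity"))
        assert np.abs(out - img).max() < 1.0

    def test_lr_equals_rl_with_zero_guide(self, texture64, rng):
        from rldamp.denoisers import GUIDE_DENOISERS

        noisy = texture64 + rng.normal(0, 10, texture64.shape)
        GUIDE_DENOISERS["zero"] = lambda n_, s_: np.zeros_like(n_)
        try:
            rl = lsm_image_denoiser(noisy, 100.0, DenoiserConfig(guide="zero"))
            lr = lr_amp_denoiser(noisy, 100.0, DenoiserConfig(guide="zero"))
            assert np.abs(rl - lr).max() < 1e-10
        finally:
            del GUIDE_DENOISERS["zero"]

    def test_spectrum_domain_config_runs(self, texture64, rng):
        noisy = texture64 + rng.normal(0, 20, texture64.shape)
        out = lsm_image_denoiser(noisy, 400.0, DenoiserConfig(shrink_domain="spectrum"))
        assert out.shape == noisy.shape and np.all(np.isfinite(out))

    def test_unknown_shrink_domain_rejected(self, texture64):
        with pytest.raises(ConfigurationError):
            lsm_image_denoiser(texture64, 1.0, DenoiserConfig(shrink_domain="bogus"))


class TestWaveletDenoise:
    def test_zero_sigma_identity(self, rng):
        img = rng.normal(size=(32, 32))
        assert np.array_equal(wavelet_denoise(img, 0.0), img)

    def test_threshold_removes_noise(self, phantom64, rng):
        noisy = phantom64 + rng.normal(0, 15, phantom64.shape)
        out = wavelet_denoise(noisy, 15.0)
        assert np.mean((out - phantom64) ** 2) < np.mean((noisy - phantom64) ** 2)
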