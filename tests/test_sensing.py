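"""Sampling masks and the partial-Fourier operator: exactness and identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rldamp import (
    FourierOperator,
    SamplingMask,
    add_measurement_noise,
    generate_vd_mask,
)
from rldamp.sensing import generate_nested_masks
from rldamp.exceptions import DimensionError, ParameterError


class TestMaskGeneration:
    def test_full_sampling_is_all_true(self):
        mask = generate_vd_mask((32, 48), 1.0, seed=0)
        assert mask.sampled.all()

    def test_cardinality_exact_at_stated_ratio(self):
        mask = generate_vd_mask((256, 256), 0.2, seed=3)
        assert mask.m == 13107  # round(0.2 * 65536)

    @pytest.mark.parametrize("shape", [(32, 32), (48, 64), (128, 128)])
    def test_cardinality_exact_over_ratio_grid(self, shape):
        for ratio in np.linspace(0.05, 1.0, 20):
            mask = generate_vd_mask(shape, float(ratio), seed=1)
            assert mask.m == round(ratio * shape[0] * shape[1])

    def test_dc_always_sampled(self):
        for ratio in (0.01, 0.1, 0.5):
            mask = generate_vd_mask((64, 64), ratio, center_fraction=0.0, seed=9)
            assert mask.sampled[32, 32]

    def test_density_decreases_with_radial_frequency(self):
        # Monte-Carlo over 200 seeds: innermost annulus denser than outermost
        shape = (128, 128)
        acc = np.zeros(shape)
        for seed in range(200):
            acc += generate_vd_mask(shape, 0.2, seed=seed).sampled
        r = np.hypot(*np.meshgrid(np.arange(128) - 64, np.arange(128) - 64, indexing="ij"))
        inner = acc[r < 8].mean()
        outer = acc[r > 56].mean()
        assert inner > outer

    def test_density_nonincreasing_over_annuli(self):
        shape = (128, 128)
        acc = np.zeros(shape)
        for seed in range(100):
            acc += generate_vd_mask(shape, 0.2, seed=seed).sampled
        r = np.hypot(*np.meshgrid(np.arange(128) - 64, np.arange(128) - 64, indexing="ij"))
        edges = [0, 8, 16, 24, 32, 40, 48, 56, 64]
        means = [
            acc[(r >= lo) & (r < hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert all(a >= b - 1e-9 for a, b in zip(means[:-1], means[1:]))

    def test_seeded_determinism(self):
        a = generate_vd_mask((64, 64), 0.3, seed=5)
        b = generate_vd_mask((64, 64), 0.3, seed=5)
        assert np.array_equal(a.sampled, b.sampled)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            generate_vd_mask((64, 64), 0.0, seed=0)
        with pytest.raises(ParameterError):
            generate_vd_mask((64, 64), 1.5, seed=0)
        with pytest.raises(ParameterError):
            generate_vd_mask((64, 64), 0.2, center_fraction=1.5, seed=0)
        with pytest.raises(ParameterError):
            generate_vd_mask((4, 4), 0.01, seed=0)  # budget < 1 coefficient

    def test_save_load_round_trip(self, tmp_path):
        mask = generate_vd_mask((32, 32), 0.25, seed=4)
        mask.save(tmp_path / "mask.txt")
        loaded = SamplingMask.load(tmp_path / "mask.txt")
        assert np.array_equal(loaded.sampled, mask.sampled)
        assert loaded.ratio == mask.ratio and loaded.seed == mask.seed


class TestNestedMasks:
    def test_lower_ratios_are_subsets(self):
        masks = generate_nested_masks((64, 64), (0.1, 0.2, 0.3), seed=4)
        assert not np.any(masks[0.1].sampled & ~masks[0.2].sampled)
        assert not np.any(masks[0.2].sampled & ~masks[0.3].sampled)

    def test_cardinality_and_dc(self):
        masks = generate_nested_masks((64, 64), (0.15, 0.4), seed=1)
        for ratio, mask in masks.items():
            assert mask.m == round(ratio * 4096)
            assert mask.sampled[32, 32]

    def test_density_is_low_frequency_heavy(self):
        acc = np.zeros((64, 64))
        for seed in range(100):
            acc += generate_nested_masks((64, 64), (0.2,), seed=seed)[0.2].sampled
        r = np.hypot(*np.meshgrid(np.arange(64) - 32, np.arange(64) - 32, indexing="ij"))
        assert acc[r < 4].mean() > acc[r > 28].mean()


class TestFourierOperator:
    def test_constant_image_hits_only_dc(self):
        mask = generate_vd_mask((16, 16), 1.0, seed=0)
        op = FourierOperator(mask)
        y = op.forward(np.full((16, 16), 3.0))
        grid = y.reshape(16, 16)
        assert abs(grid[8, 8] - 3.0 * 16) < 1e-10  # c * sqrt(rows*cols)
        grid[8, 8] = 0
        assert np.abs(grid).max() < 1e-10

    def test_zero_image_maps_to_zero(self):
        op = FourierOperator(generate_vd_mask((16, 16), 0.3, seed=0))
        assert np.abs(op.forward(np.zeros((16, 16)))).max() == 0

    def test_parseval_at_full_sampling(self, rng):
        op = FourierOperator(generate_vd_mask((32, 32), 1.0, seed=0))
        x = rng.normal(size=(32, 32))
        assert abs(np.linalg.norm(op.forward(x)) - np.linalg.norm(x)) < 1e-10

    def test_forward_never_expands_norm(self, rng):
        op = FourierOperator(generate_vd_mask((32, 32), 0.4, seed=2))
        for _ in range(10):
            x = rng.normal(size=(32, 32))
            assert np.linalg.norm(op.forward(x)) <= np.linalg.norm(x) + 1e-12

    def test_full_mask_round_trip(self, rng):
        op = FourierOperator(generate_vd_mask((32, 32), 1.0, seed=0))
        x = rng.normal(size=(32, 32))
        assert np.abs(op.adjoint(op.forward(x)) - x).max() < 1e-10

    def test_forward_adjoint_identity_on_measurements(self, rng):
        op = FourierOperator(generate_vd_mask((32, 32), 0.3, seed=1))
        y = rng.normal(size=op.m) + 1j * rng.normal(size=op.m)
        assert np.abs(op.forward(op.adjoint(y)) - y).max() < 1e-10

    def test_projection_idempotent_and_self_adjoint(self, rng):
        op = FourierOperator(generate_vd_mask((32, 32), 0.3, seed=1))
        x = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        p1 = op.adjoint(op.forward(x))
        p2 = op.adjoint(op.forward(p1))
        assert np.abs(p2 - p1).max() < 1e-10

    def test_adjointness_inner_product_identity(self, rng):
        op = FourierOperator(generate_vd_mask((24, 24), 0.35, seed=7))
        for _ in range(50):
            x = rng.normal(size=(24, 24))
            y = rng.normal(size=op.m) + 1j * rng.normal(size=op.m)
            lhs = np.vdot(y, op.forward(x))
            rhs = np.vdot(op.adjoint(y), x.astype(complex))
            assert abs(lhs - rhs) < 1e-10 * max(1.0, abs(lhs))

    def test_shape_mismatch_rejected(self):
        op = FourierOperator(generate_vd_mask((16, 16), 0.5, seed=0))
        with pytest.raises(DimensionError):
            op.forward(np.zeros((8, 8)))
        with pytest.raises(DimensionError):
            op.adjoint(np.zeros(3, dtype=complex))


class TestMeasurementNoise:
    def test_zero_sigma_is_identity(self, rng):
        y = rng.normal(size=100) + 1j * rng.normal(size=100)
        assert np.array_equal(add_measurement_noise(y, 0.0, seed=1), y)

    def test_total_variance_matches_sigma_squared(self):
        y = np.zeros(10**4, dtype=complex)
        noisy = add_measurement_noise(y, 8.0, seed=3)
        var = np.mean(np.abs(noisy) ** 2)
        assert abs(var - 64.0) / 64.0 < 0.05

    def test_same_seed_bit_identical(self, rng):
        y = rng.normal(size=50) + 0j
        a = add_measurement_noise(y, 5.0, seed=11)
        b = add_measurement_noise(y, 5.0, seed=11)
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            add_measurement_noise(np.zeros(4, dtype=complex), -1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    ratio=st.floats(0.05, 1.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_mask_invariants_hold_for_any_ratio_and_seed(ratio, seed):
    mask = generate_vd_mask((32, 32), ratio, seed=seed)
    assert mask.m == round(ratio * 1024)
    assert mask.sampled[16, 16]  # DC
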