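"""SPEND pairing, noise diagnostics, network training, SNR metrics."""

import numpy as np
import pytest

import filmspec as fs
from filmspec._nn import ConvNet3d, mse_loss
from filmspec.denoise import (
    DenoiserConfig,
    SpendDenoiser,
    compute_snr,
    denoise,
    diagnose_noise_correlation,
    make_permutation_pair,
    permutation_indices,
    train_denoiser,
)
from filmspec.errors import ConfigError, EmptySelectionError
from filmspec.synthetic import correlated_noise


def _stack_from(data, start=1000.0):
    n = data.shape[2]
    axis = fs.make_axis(start, start + 10 * (n - 1), n)
    return fs.HyperStack(data, axis)


class TestPermutationPairing:
    def test_six_frame_split(self, rng):
        stack = _stack_from(rng.uniform(0, 1, (4, 4, 6)))
        pair = make_permutation_pair(stack)
        np.testing.assert_array_equal(pair.input_indices, [0, 2, 4])
        np.testing.assert_array_equal(pair.target_indices, [1, 3, 5])
        np.testing.assert_array_equal(pair.input_data, stack.data[:, :, [0, 2, 4]])
        np.testing.assert_array_equal(pair.target_data, stack.data[:, :, [1, 3, 5]])

    def test_identical_frames_give_identical_halves(self):
        frame = np.arange(16.0).reshape(4, 4)
        stack = _stack_from(np.repeat(frame[:, :, None], 6, axis=2))
        pair = make_permutation_pair(stack)
        np.testing.assert_array_equal(pair.input_data, pair.target_data)

    def test_odd_length_split(self, rng):
        stack = _stack_from(rng.uniform(0, 1, (4, 4, 5)))
        pair = make_permutation_pair(stack)
        np.testing.assert_array_equal(pair.input_indices, [0, 2, 4])
        np.testing.assert_array_equal(pair.target_indices, [1, 3])

    @pytest.mark.parametrize("n", list(range(2, 201)))
    def test_parity_partition_exhaustive(self, n):
        """Input/target index sets are disjoint and jointly exhaustive with a
        length difference of at most 1, for every stack length 2..200."""
        even, odd = permutation_indices(n)
        assert set(even).isdisjoint(odd)
        assert sorted(np.concatenate([even, odd])) == list(range(n))
        assert abs(len(even) - len(odd)) <= 1

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            permutation_indices(1)

    def test_swapped_pair_mirrors(self, rng):
        stack = _stack_from(rng.uniform(0, 1, (4, 4, 8)))
        pair, swapped = make_permutation_pair(stack, with_swapped=True)
        np.testing.assert_array_equal(pair.input_data, swapped.target_data)
        np.testing.assert_array_equal(pair.target_data, swapped.input_data)

    def test_half_stacks_carry_subsampled_axis(self, rng):
        stack = _stack_from(rng.uniform(0, 1, (4, 4, 8)))
        pair = make_permutation_pair(stack)
        np.testing.assert_allclose(pair.input_stack.axis.values, stack.axis.values[::2])


class TestNoiseDiagnostics:
    def test_row_correlated_noise_detected(self):
        noise = correlated_noise((48, 48, 32), 1.0, corr_len_px=5, axis="row", seed=1)
        diag = diagnose_noise_correlation(noise)
        assert diag.dominant_axis == "row"
        assert diag.lag1["row"] > 0.5

    @pytest.mark.parametrize("ax", ["row", "col", "frame"])
    def test_dominant_axis_follows_simulation(self, ax):
        noise = correlated_noise((40, 40, 40), 1.0, corr_len_px=4, axis=ax, seed=3)
        assert diagnose_noise_correlation(noise).dominant_axis == ax

    def test_white_noise_near_zero_everywhere(self):
        noise = correlated_noise((64, 64, 64), 1.0, corr_len_px=0, seed=2)
        diag = diagnose_noise_correlation(noise)
        for value in diag.lag1.values():
            assert abs(value) < 0.05

    def test_constant_stack_flagged_undefined(self):
        diag = diagnose_noise_correlation(np.ones((8, 8, 8)))
        assert diag.undefined
        assert diag.dominant_axis is None


@pytest.fixture(scope="module")
def tiny_config():
    return DenoiserConfig(
        depth=2, base_channels=4, epochs=4, steps_per_epoch=6,
        patch_shape=(16, 16, 8), seed=5, lr_schedule=(),
    )


@pytest.fixture(scope="module")
def tiny_noisy_stack():
    rng = np.random.default_rng(8)
    clean = np.zeros((32, 32, 16))
    clean[8:16, 8:16, :] = np.linspace(1.0, 2.0, 16)
    clean[20:26, 20:26, :] = np.linspace(2.0, 1.0, 16)
    noisy = clean + rng.normal(0, 0.5, clean.shape)
    return _stack_from(noisy), clean


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        net = ConvNet3d(base_channels=2, depth=2, seed=0)
        for conv in net.convs():
            conv.w = conv.w.astype(np.float64)
            conv.b = conv.b.astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 1, 4, 4, 4))
        y = rng.standard_normal((1, 1, 4, 4, 4))
        loss, grad = mse_loss(net.forward(x, train=True), y)
        net.backward(grad)
        eps = 1e-6
        for conv in net.convs():
            analytic = conv.gw.copy()
            flat = np.argsort(-np.abs(analytic).ravel())[:4]
            for f in flat:
                idx = np.unravel_index(f, analytic.shape)
                w0 = conv.w[idx]
                conv.w[idx] = w0 + eps
                lp, _ = mse_loss(net.forward(x, train=False), y)
                conv.w[idx] = w0 - eps
                lm, _ = mse_loss(net.forward(x, train=False), y)
                conv.w[idx] = w0
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(analytic[idx], rel=1e-4, abs=1e-9)

    def test_shape_preserved_and_odd_dims_rejected(self):
        net = ConvNet3d(base_channels=2, depth=2, seed=0)
        out = net.forward(np.zeros((1, 1, 8, 8, 8), dtype=np.float32), train=False)
        assert out.shape == (1, 1, 8, 8, 8)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 7, 8, 8), dtype=np.float32), train=False)


class TestTraining:
    def test_loss_decreases_on_identity_task(self, rng, tiny_config):
        frame = rng.uniform(0, 1, (24, 24))
        stack = _stack_from(np.repeat(frame[:, :, None], 16, axis=2))
        model = train_denoiser(make_permutation_pair(stack), tiny_config)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_seeded_determinism(self, tiny_noisy_stack, tiny_config):
        stack, _ = tiny_noisy_stack
        pair = make_permutation_pair(stack)
        m1 = train_denoiser(pair, tiny_config)
        m2 = train_denoiser(pair, tiny_config)
        assert m1.loss_trace[-1] == pytest.approx(m2.loss_trace[-1], abs=1e-6)

    def test_denoising_reduces_mse_to_clean(self, tiny_noisy_stack, tiny_config):
        stack, clean = tiny_noisy_stack
        pair = make_permutation_pair(stack)
        config = DenoiserConfig(
            depth=2, base_channels=4, epochs=10, steps_per_epoch=10,
            patch_shape=(16, 16, 8), seed=5,
        )
        model = train_denoiser(pair, config)
        out = denoise(model, stack)
        assert out.data.shape == stack.data.shape
        assert out.axis == stack.axis
        mse_raw = np.mean((stack.data - clean) ** 2)
        mse_den = np.mean((out.data - clean) ** 2)
        assert mse_den < mse_raw
        # spectral smoothing: total frame-to-frame variation decreases
        region = clean[:, :, 0] > 0
        tv_raw = np.abs(np.diff(stack.data[region], axis=-1)).sum()
        tv_den = np.abs(np.diff(out.data[region], axis=-1)).sum()
        assert tv_den < tv_raw

    def test_noiseless_input_nearly_passed_through(self, tiny_noisy_stack):
        """Noise2Noise mean-prediction property: a model trained at noise
        level sigma perturbs a noiseless stack by less than sigma^2 in MSE."""
        stack, clean = tiny_noisy_stack
        sigma = 0.5  # training noise level of the fixture
        config = DenoiserConfig(
            depth=2, base_channels=4, epochs=8, steps_per_epoch=8,
            patch_shape=(16, 16, 8), seed=5,
        )
        model = train_denoiser(make_permutation_pair(stack), config)
        clean_stack = _stack_from(clean)
        out = model.apply(clean_stack, clip_negative=False)
        assert np.mean((out.data - clean) ** 2) < sigma**2

    def test_constant_stack_maps_to_constant(self, tiny_config):
        stack = _stack_from(np.full((24, 24, 16), 3.0))
        pair = make_permutation_pair(stack)
        model = train_denoiser(pair, tiny_config)
        out = model.apply(stack, clip_negative=False)
        assert np.ptp(out.data) <= 0.01 * 3.0

    def test_patch_larger_than_stack_rejected(self, tiny_noisy_stack):
        stack, _ = tiny_noisy_stack
        pair = make_permutation_pair(stack)
        config = DenoiserConfig(patch_shape=(64, 64, 64))
        with pytest.raises(ConfigError):
            train_denoiser(pair, config)

    def test_model_round_trip(self, tmp_path, tiny_noisy_stack, tiny_config):
        stack, _ = tiny_noisy_stack
        model = train_denoiser(make_permutation_pair(stack), tiny_config)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SpendDenoiser.load(path)
        out1 = model.apply(stack)
        out2 = loaded.apply(stack)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_negative_clipping_flagged(self, tiny_noisy_stack, tiny_config):
        stack, _ = tiny_noisy_stack
        model = train_denoiser(make_permutation_pair(stack), tiny_config)
        out = model.apply(stack, clip_negative=True)
        assert out.data.min() >= 0
        assert "denoise_clipped_negative_px" in out.meta


class TestSnr:
    def test_constructed_ratio_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1.0, (64, 64, 8))
        data[16:32, 16:32, :] += 10.0
        stack = _stack_from(data)
        signal = np.zeros((64, 64), dtype=bool)
        signal[16:32, 16:32] = True
        background = np.zeros((64, 64), dtype=bool)
        background[40:, :] = True  # >1e3 px
        report = compute_snr(stack, signal, background)
        assert report.image_snr == pytest.approx(10.0, rel=0.1)
        assert not report.saturated

    def test_zero_noise_background_saturates(self):
        data = np.zeros((8, 8, 6))
        data[2:4, 2:4, :] = 5.0
        stack = _stack_from(data)
        signal = data[:, :, 0] > 0
        report = compute_snr(stack, signal, ~signal)
        assert np.isinf(report.image_snr)
        assert report.saturated

    def test_overlapping_masks_rejected(self, small_stack):
        mask = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError):
            compute_snr(small_stack, mask, mask)
        with pytest.raises(EmptySelectionError):
            compute_snr(small_stack, np.zeros((8, 8), bool), mask)
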