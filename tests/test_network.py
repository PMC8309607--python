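import numpy as np
import pytest

from ramandenoise import (
    DenoiserCNN,
    LayerSpec,
    NetworkSpec,
    build_network,
    count_parameters,
    default_network_spec,
    denoise,
    load_model,
    save_model,
)


@pytest.fixture(scope="module")
def tiny_spec():
    """A miniature network with every convolution strategy represented:
    single-channel narrow (im2col), multi-channel (shift-matmul), even
    widths (asymmetric padding) and a full-width single-channel output
    (FFT path)."""
    return NetworkSpec(input_length=70, layers=(
        LayerSpec(1, 3, 3, True),
        LayerSpec(2, 2, 4, True),
        LayerSpec(3, 1, 9, True),
        LayerSpec(4, 1, 70, False),
    ))


class TestArchitecture:
    def test_reference_parameter_counts(self):
        assert count_parameters(default_network_spec()) == \
            [2560, 163968, 41024, 577, 601]

    def test_built_model_matches_spec_counts(self):
        model = build_network(seed=0)
        assert model.n_conv_parameters() == [2560, 163968, 41024, 577, 601]
        # batch-norm affine parameters exist but are tallied separately
        assert model.n_batchnorm_parameters() == 2 * (256 + 128 + 64 + 1)

    def test_every_feature_map_keeps_input_width(self):
        model = build_network(seed=0)
        x = np.random.default_rng(0).uniform(0, 4000, (2, 600))
        maps = model.feature_maps(x)
        assert [m.shape for m in maps] == [
            (2, 600, 256), (2, 600, 128), (2, 600, 64), (2, 600, 1),
            (2, 600, 1)]

    def test_layer_index_order_enforced(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_length=600, layers=(
                LayerSpec(2, 4, 3, True), LayerSpec(1, 1, 3, False)))

    def test_kernel_cannot_exceed_input(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_length=10, layers=(LayerSpec(1, 1, 11, False),))


class TestForward:
    def test_output_width_equals_input_width(self, tiny_spec):
        model = DenoiserCNN(tiny_spec, seed=1)
        out = model.forward(np.ones((3, 70)))
        assert out.shape == (3, 70)

    def test_batch_order_preserved(self, tiny_spec, rng):
        model = DenoiserCNN(tiny_spec, seed=1)
        x = rng.uniform(0, 100, (5, 70))
        batch = model.forward(x)
        singles = np.stack([model.forward(x[i:i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(batch, singles, rtol=1e-5, atol=1e-4)

    def test_same_seed_same_initial_weights(self, tiny_spec):
        a = DenoiserCNN(tiny_spec, seed=9)
        b = DenoiserCNN(tiny_spec, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = DenoiserCNN(tiny_spec, seed=10)
        assert any(not np.array_equal(pa.value, pc.value)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_inference_is_repeatable(self, tiny_spec, rng):
        model = DenoiserCNN(tiny_spec, seed=2)
        x = rng.uniform(0, 50, (4, 70))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_wrong_length_rejected_with_expected_length(self, tiny_spec):
        model = DenoiserCNN(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="70"):
            model.forward(np.ones((2, 64)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_spec):
        model = DenoiserCNN(tiny_spec, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (4, 70))
        t = rng.normal(0, 1, (4, 70))
        w = rng.uniform(0.5, 2.0, (4, 70))

        def loss():
            e = model.forward(x, training=True) - t
            return float(np.mean(np.sum(w * e * e, axis=1)))

        out = model.forward(x, training=True)
        model.zero_grad()
        model.backward((2.0 / 4) * w * (out - t))
        eps = 1e-5
        for p in model.parameters():
            grad = p.grad.copy()
            it = np.nditer(p.value, flags=["multi_index"])
            for _ in range(min(p.value.size, 12)):
                idx = it.multi_index
                orig = p.value[idx]
                p.value[idx] = orig + eps
                lp = loss()
                p.value[idx] = orig - eps
                lm = loss()
                p.value[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                if max(abs(numeric), abs(grad[idx])) > 1e-6:
                    assert numeric == pytest.approx(grad[idx], rel=1e-4), \
                        f"param shape {p.value.shape} index {idx}"
                it.iternext()


class TestDenoiseApi:
    def test_spectrum_in_spectrum_out(self, noisy_pair):
        model = build_network(seed=0)
        out = denoise(model, noisy_pair.noisy)
        assert len(out) == len(noisy_pair.noisy)
        assert out.axis is noisy_pair.noisy.axis

    def test_list_and_matrix_agree(self, small_dataset):
        model = build_network(seed=0)
        spectra = [p.noisy for p in small_dataset[:3]]
        as_list = denoise(model, spectra)
        as_matrix = denoise(model, np.stack([s.intensity for s in spectra]))
        for s, row in zip(as_list, as_matrix):
            np.testing.assert_allclose(s.intensity, row, rtol=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_spec, tmp_path, rng):
        model = DenoiserCNN(tiny_spec, seed=4)
        x = rng.uniform(0, 10, (2, 70)).astype(np.float32)
        # push some training so running stats are non-trivial
        out = model.forward(x, training=True)
        model.zero_grad()
        model.backward(out - x)
        for p in model.parameters():
            p.value -= 1e-6 * p.grad
        expected = model.forward(x)
        save_model(model, tmp_path / "model.npz")
        restored = load_model(tmp_path / "model.npz")
        np.testing.assert_allclose(restored.forward(x), expected, rtol=1e-6)
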