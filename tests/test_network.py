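"""Unit tests for the CNN architecture, forward pass, and weight codec."""

import numpy as np
import pytest

import gacnn as g
from gacnn.network import ArchitectureError, forward_batch, _conv_batch, _pool_batch


def brute_force_conv(x, filters, biases):
    """Quadruple-loop convolution oracle, independent of the implementation."""
    n_f, k, _, _ = filters.shape
    h, w, _ = x.shape
    out = np.zeros((h - k + 1, w - k + 1, n_f))
    for f in range(n_f):
        for i in range(h - k + 1):
            for j in range(w - k + 1):
                out[i, j, f] = np.sum(x[i : i + k, j : j + k, :] * filters[f]) + biases[f]
    return out


class TestBuildNetwork:
    def test_default_architecture_shape_chain(self):
        # 210 -> 208 -> 206 -> 103 -> 101 -> 99 -> 49 -> 47 -> 45 -> 22 -> 20 -> 18 -> 9
        spec = g.build_network()
        assert spec.layers[-1][1] == (9, 9, 32)
        assert spec.flatten_size == 9 * 9 * 32 == 2592

    def test_small_example(self):
        spec = g.build_network((8, 8, 1), [2], pool_every=1)
        assert spec.layers[-1][1] == (3, 3, 2)

    def test_impossible_second_conv_raises(self):
        with pytest.raises(ArchitectureError):
            g.build_network((4, 4, 1), [2, 2])

    @pytest.mark.parametrize("bad", [(0, 8, 1), (8, -1, 3)])
    def test_nonpositive_input_rejected(self, bad):
        with pytest.raises(ArchitectureError):
            g.build_network(bad, [2])

    def test_flatten_size_matches_probe_image(self, small_spec):
        ws = g.init_weights(small_spec, "uniform", 3)
        x = np.random.default_rng(0).uniform(size=(1, *small_spec.input_shape))
        conv_i, t = 0, x
        for layer in small_spec.layers:
            if layer[0] == "conv":
                t = np.maximum(_conv_batch(t, ws.conv_filters[conv_i], ws.conv_biases[conv_i]), 0)
                conv_i += 1
            else:
                t = _pool_batch(t)
        assert t[0].size == small_spec.flatten_size


class TestCountWeights:
    def test_tiny_spec_by_enumeration(self, tiny_spec):
        # conv: 2*(3*3*1)+2 = 20; dense: (3*3*2)*2+2 = 38
        assert g.count_weights(tiny_spec) == 58

    def test_default_spec(self):
        spec = g.build_network()  # hidden_width 100, biases on
        # 29016 conv weights + 160 conv biases + 259200 + 100 + 200 + 2
        assert g.count_weights(spec) == 288678

    def test_dense_only_case(self):
        spec = g.build_network((5, 4, 1), [], hidden_width=0, use_biases=False)
        assert g.count_weights(spec) == 2 * 20


class TestInitWeights:
    def test_seeded_determinism(self, small_spec):
        a = g.init_weights(small_spec, "uniform", seed=1)
        b = g.init_weights(small_spec, "uniform", seed=1)
        assert a == b

    def test_uniform_range(self, small_spec):
        v = g.flatten_weights(g.init_weights(small_spec, "uniform", seed=2))
        assert np.all(v >= -0.1) and np.all(v <= 0.1)

    def test_normal_sample_mean_clt(self):
        spec = g.build_network((16, 16, 3), [4, 4], hidden_width=20)
        v = g.flatten_weights(g.init_weights(spec, "normal", seed=3))
        assert abs(v.mean()) <= 3 * 0.1 / np.sqrt(v.size)

    def test_unknown_distribution(self, small_spec):
        with pytest.raises(ValueError):
            g.init_weights(small_spec, "cauchy", seed=0)


class TestConvolveValid:
    def test_all_ones(self):
        out = g.convolve_valid(np.ones((4, 4, 1)), np.ones((1, 3, 3, 1)), [0.0])
        assert out.shape == (2, 2, 1)
        assert np.allclose(out, 9.0)

    def test_zero_filter_annihilates(self, rng):
        x = rng.normal(size=(5, 5, 2))
        out = g.convolve_valid(x, np.zeros((3, 3, 3, 2)), np.zeros(3))
        assert np.all(out == 0)

    def test_self_filter_gives_sum_of_squares(self, rng):
        x = rng.normal(size=(3, 3, 1))
        out = g.convolve_valid(x, x[None], [0.0])
        assert out.shape == (1, 1, 1)
        assert np.allclose(out[0, 0, 0], np.sum(x**2))

    def test_bias_added_per_filter(self, rng):
        x = rng.normal(size=(4, 4, 1))
        f = rng.normal(size=(2, 3, 3, 1))
        with_b = g.convolve_valid(x, f, [1.0, -2.0])
        no_b = g.convolve_valid(x, f, [0.0, 0.0])
        assert np.allclose(with_b - no_b, np.array([1.0, -2.0]))

    def test_depth_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            g.convolve_valid(rng.normal(size=(4, 4, 2)), rng.normal(size=(1, 3, 3, 1)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 6, 2))
        f = rng.normal(size=(3, 3, 3, 2))
        b = rng.normal(size=3)
        assert np.allclose(g.convolve_valid(x, f, b), brute_force_conv(x, f, b), atol=1e-12)


class TestAveragePool:
    def test_constant_map(self):
        out = g.average_pool(np.full((4, 4, 2), 3.7))
        assert out.shape == (2, 2, 2)
        assert np.allclose(out, 3.7)

    def test_hand_computed_blocks(self):
        x = np.arange(1, 17, dtype=float).reshape(4, 4)
        assert np.allclose(g.average_pool(x), [[3.5, 5.5], [11.5, 13.5]])

    def test_odd_dimension_truncates(self, rng):
        x = rng.normal(size=(5, 5, 1))
        assert np.allclose(g.average_pool(x), g.average_pool(x[:4, :4, :]))

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            g.average_pool(np.ones((1, 4, 1)))


class TestActivations:
    def test_relu(self):
        assert np.array_equal(g.relu([-3, 0, 5]), [0, 0, 5])
        assert np.all(g.relu(-np.ones(4)) == 0)
        x = np.array([0.5, 2.0])
        assert np.array_equal(g.relu(x), x)

    def test_sigmoid_midpoint_symmetry_saturation(self):
        assert g.sigmoid(0.0) == 0.5
        for x in (-3.2, 0.7, 10.0):
            assert g.sigmoid(x) == pytest.approx(1 - g.sigmoid(-x))
        assert g.sigmoid(100.0) == pytest.approx(1.0, abs=1e-6)
        # no overflow warnings for extreme inputs
        with np.errstate(over="raise"):
            assert g.sigmoid(-1000.0) == pytest.approx(0.0, abs=1e-12)

    def test_dense_forward(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(g.dense_forward(x, np.eye(3), np.zeros(3)), x)
        assert g.dense_forward([3.0], [[2.0]], [1.0])[0] == 7.0
        assert np.allclose(g.dense_forward(x, np.zeros((2, 3)), [4.0, 5.0]), [4.0, 5.0])
        with pytest.raises(ValueError):
            g.dense_forward(x, np.eye(2), np.zeros(2))


class TestForwardPredict:
    def test_scores_normalized(self, small_spec, rng):
        ws = g.init_weights(small_spec, "uniform", 5)
        imgs = rng.uniform(size=(4, *small_spec.input_shape))
        scores = forward_batch(small_spec, ws, imgs)
        assert np.allclose(scores.sum(axis=1), 1.0)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_zero_weights_uniform_scores(self):
        spec = g.build_network((8, 8, 1), [2], pool_every=1, hidden_width=0, use_biases=False)
        ws = g.restore_weights(np.zeros(g.count_weights(spec)), spec)
        scores = g.forward(spec, ws, np.random.default_rng(0).uniform(size=(8, 8, 1)))
        assert np.allclose(scores, [0.5, 0.5])

    def test_forward_equals_layer_composition(self, small_spec, rng):
        """End-to-end forward must equal explicitly composing the layer ops."""
        ws = g.init_weights(small_spec, "uniform", 7)
        for _ in range(10):
            img = rng.uniform(size=small_spec.input_shape)
            x, conv_i = img, 0
            for layer in small_spec.layers:
                if layer[0] == "conv":
                    x = g.relu(g.convolve_valid(x, ws.conv_filters[conv_i], ws.conv_biases[conv_i]))
                    conv_i += 1
                else:
                    x = g.average_pool(x)
            flat = x.ravel()
            hidden = g.relu(g.dense_forward(flat, ws.dense_weights[0], ws.dense_biases[0]))
            logits = g.dense_forward(hidden, ws.dense_weights[1], ws.dense_biases[1])
            expected = np.exp(logits - logits.max())
            expected /= expected.sum()
            assert np.allclose(g.forward(small_spec, ws, img), expected, atol=1e-12)

    def test_forward_deterministic(self, small_spec, rng):
        ws = g.init_weights(small_spec, "uniform", 11)
        img = rng.uniform(size=small_spec.input_shape)
        assert np.array_equal(g.forward(small_spec, ws, img), g.forward(small_spec, ws, img))

    def test_predict_ties_to_benign(self):
        spec = g.build_network((8, 8, 1), [2], pool_every=1, hidden_width=0, use_biases=False)
        ws = g.restore_weights(np.zeros(g.count_weights(spec)), spec)
        assert g.predict(spec, ws, np.ones((2, 8, 8, 1))).tolist() == [0, 0]

    def test_predict_matches_per_image_argmax(self, small_spec, rng):
        ws = g.init_weights(small_spec, "uniform", 13)
        imgs = rng.uniform(size=(6, *small_spec.input_shape))
        batch = g.predict(small_spec, ws, imgs)
        single = [int(np.argmax(g.forward(small_spec, ws, im))) for im in imgs]
        assert batch.tolist() == single

    def test_sigmoid_output_mode_normalized(self, rng):
        spec = g.build_network((8, 8, 1), [2], pool_every=1, hidden_width=0,
                               output_mode="sigmoid")
        ws = g.init_weights(spec, "uniform", 5)
        scores = g.forward(spec, ws, rng.uniform(size=(8, 8, 1)))
        assert scores.sum() == pytest.approx(1.0)


class TestWeightCodec:
    def test_round_trip_bijection(self, small_spec):
        ws = g.init_weights(small_spec, "normal", 17)
        v = g.flatten_weights(ws)
        assert v.size == g.count_weights(small_spec)
        back = g.restore_weights(v, small_spec)
        assert back == ws
        assert np.array_equal(g.flatten_weights(back), v)

    def test_single_parameter_locality(self, small_spec):
        ws1 = g.init_weights(small_spec, "uniform", 19)
        ws2 = ws1.copy()
        ws2.conv_filters[1][0, 1, 2, 0] += 0.5
        diff = g.flatten_weights(ws1) != g.flatten_weights(ws2)
        assert diff.sum() == 1

    def test_wrong_length_raises(self, small_spec):
        with pytest.raises(ValueError):
            g.restore_weights(np.zeros(g.count_weights(small_spec) + 1), small_spec)

    def test_zero_vector_restores_zero_set(self, tiny_spec):
        ws = g.restore_weights(np.zeros(58), tiny_spec)
        assert all(np.all(t == 0) for t in ws.tensors())
        assert ws.conv_filters[0].shape == (2, 3, 3, 1)


class TestCheckpoint:
    def test_round_trip(self, small_spec, tmp_path):
        ws = g.init_weights(small_spec, "normal", 23)
        path = tmp_path / "ckpt.npz"
        g.save_checkpoint(path, small_spec, ws)
        spec2, ws2 = g.load_checkpoint(path)
        assert spec2 == small_spec
        assert ws2 == ws
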