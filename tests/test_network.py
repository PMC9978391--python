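import numpy as np
import pytest

from dwisr.network import (
    ModelState,
    SRCNNSpec,
    forward,
    forward_backward,
    init_model,
    load_checkpoint,
    save_checkpoint,
)


def conv3d_reference(x, weights, bias):
    """Nested-loop direct 3-D cross-correlation with zero 'same' padding.

    Deliberately naive; the oracle for the GEMM-based implementation.
    """
    c_out, c_in, k = weights.shape[0], weights.shape[1], weights.shape[2]
    p = k // 2
    X, Y, Z = x.shape[1:]
    out = np.zeros((c_out, X, Y, Z))
    for o in range(c_out):
        for i in range(X):
            for j in range(Y):
                for l in range(Z):
                    acc = 0.0
                    for c in range(c_in):
                        for a in range(k):
                            for b in range(k):
                                for d in range(k):
                                    ii, jj, ll = i + a - p, j + b - p, l + d - p
                                    if 0 <= ii < X and 0 <= jj < Y and 0 <= ll < Z:
                                        acc += x[c, ii, jj, ll] * weights[o, c, a, b, d]
                    out[o, i, j, l] = acc + bias[o]
    return out


def forward_reference(model, x):
    """f(x) through the loop oracle, then the residual average."""
    a = x[np.newaxis]
    n = len(model.weights)
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        a = conv3d_reference(a, w, b)
        if i < n - 1:
            a = np.maximum(a, 0.0)
    w_res = model.spec.residual_weight
    return (1 - w_res) * x + w_res * a[0]


class TestSpec:
    def test_default_layer_shapes(self):
        shapes = SRCNNSpec().layer_shapes()
        assert shapes == [(32, 1, 9, 9, 9), (16, 32, 3, 3, 3), (1, 16, 5, 5, 5)]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SRCNNSpec(kernel_edges=(8, 3, 5))  # even kernel
        with pytest.raises(ValueError):
            SRCNNSpec(channels=(32, 16, 2))  # last channel != 1
        with pytest.raises(ValueError):
            SRCNNSpec(residual_weight=1.5)


class TestInit:
    def test_seed_determinism(self):
        a = init_model(SRCNNSpec(seed=11))
        b = init_model(SRCNNSpec(seed=11))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_init_scale_gives_zero_weights(self):
        m = init_model(SRCNNSpec(init_scale=0.0))
        assert all(np.all(w == 0) for w in m.weights)
        assert all(np.all(b == 0) for b in m.biases)


class TestForward:
    def test_zero_model_halves_input(self, rng):
        m = init_model(SRCNNSpec(init_scale=0.0, residual_weight=0.5))
        x = rng.random((9, 9, 9)) * 10
        np.testing.assert_allclose(forward(m, x), x / 2.0, atol=1e-14)

    def test_residual_weight_zero_is_identity(self, rng):
        m = init_model(SRCNNSpec(residual_weight=0.0, init_scale=0.1, seed=2))
        x = rng.random((9, 9, 9))
        np.testing.assert_array_equal(forward(m, x), x)

    @pytest.mark.parametrize("size", [5, 7])
    def test_matches_nested_loop_oracle(self, size, rng):
        spec = SRCNNSpec(
            kernel_edges=(3, 3, 3), channels=(3, 2, 1), init_scale=0.3, seed=5
        )
        m = init_model(spec)
        for b in m.biases:
            b += rng.normal(0, 0.1, b.shape)
        x = rng.random((size, size, size))
        got = forward(m, x)
        want = forward_reference(m, x)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-12)

    def test_output_shape_equals_input_shape(self, rng):
        m = init_model(SRCNNSpec(seed=0))
        for shape in [(9, 9, 9), (12, 10, 9), (15, 9, 11)]:
            assert forward(m, rng.random(shape)).shape == shape

    def test_centered_delta_kernels_give_identity(self):
        # With each layer a centered delta (summed over input channels so the
        # composition stays the identity) and nonnegative input, f(x) = x and
        # the residual average returns x for any w.
        spec = SRCNNSpec(kernel_edges=(3, 3, 3), channels=(2, 2, 1),
                         residual_weight=0.7, init_scale=0.0)
        m = init_model(spec)
        c = 1  # kernel center
        m.weights[0][0, 0, c, c, c] = 1.0  # channel 0 carries x
        m.weights[1][0, 0, c, c, c] = 1.0
        m.weights[2][0, 0, c, c, c] = 1.0
        x = np.abs(np.random.default_rng(8).random((6, 6, 6)))
        np.testing.assert_allclose(forward(m, x), x, atol=1e-12)

    def test_lipschitz_in_input(self, rng):
        # |forward(x+d) - forward(x)| <= K |d| for fixed weights
        m = init_model(SRCNNSpec(init_scale=1e-2, seed=3))
        x = rng.random((10, 10, 10))
        base = forward(m, x)
        ratios = []
        for scale in (1e-3, 1e-2, 1e-1):
            d = rng.normal(0, scale, x.shape)
            ratios.append(
                np.linalg.norm(forward(m, x + d) - base) / np.linalg.norm(d)
            )
        assert max(ratios) < 10.0

    def test_nonfinite_input_rejected(self):
        m = init_model(SRCNNSpec())
        x = np.zeros((9, 9, 9))
        x[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            forward(m, x)


class TestBackward:
    def test_gradients_match_finite_differences(self, rng):
        spec = SRCNNSpec(kernel_edges=(3, 3, 3), channels=(3, 2, 1),
                         init_scale=0.05, seed=1)
        m = init_model(spec)
        x = rng.random((6, 6, 6))
        t = rng.random((6, 6, 6))
        _, gw, gb, _ = forward_backward(m, x, t)
        eps = 1e-6
        probes = [(0, (1, 0, 2, 1, 0)), (1, (1, 2, 0, 1, 2)), (2, (0, 1, 2, 0, 1))]
        for layer, idx in probes:
            w = m.weights[layer]
            w[idx] += eps
            lp, *_ = forward_backward(m, x, t)
            w[idx] -= 2 * eps
            lm, *_ = forward_backward(m, x, t)
            w[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert gw[layer][idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        for layer in range(3):
            b = m.biases[layer]
            b[0] += eps
            lp, *_ = forward_backward(m, x, t)
            b[0] -= 2 * eps
            lm, *_ = forward_backward(m, x, t)
            b[0] += eps
            assert gb[layer][0] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        m = init_model(SRCNNSpec(seed=4, init_scale=0.01))
        m.iteration_count = 321
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        assert back.spec == m.spec
        assert back.iteration_count == 321
        for a, b in zip(m.weights, back.weights):
            np.testing.assert_array_equal(a, b)
        x = rng.random((9, 9, 9))
        np.testing.assert_array_equal(forward(m, x), forward(back, x))
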