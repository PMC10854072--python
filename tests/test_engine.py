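"""The numpy autodiff engine: every op's analytic gradient is checked
against central finite differences, and structural contracts are verified."""

import numpy as np
import pytest

from mducnn.nn import tensor as T


def numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = f()
        arr[i] = orig - eps
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def assert_grads_match(make_loss, arrays, tol=1e-4):
    tensors = [T.Tensor(a, requires_grad=True) for a in arrays]
    make_loss(tensors).backward()
    for t, a in zip(tensors, arrays):
        ng = numeric_grad(lambda: float(make_loss([T.Tensor(x) for x in arrays]).data), a)
        scale = max(1e-3, np.abs(ng).max())
        assert np.abs(t.grad - ng).max() / scale < tol


RNG = np.random.default_rng(7)
_TGT = {}


def target(shape):
    if shape not in _TGT:
        _TGT[shape] = (RNG.random(shape) > 0.5).astype(float)
    return _TGT[shape]


class TestGradients:
    def test_conv2d_k3(self):
        x = RNG.standard_normal((2, 4, 5, 3))
        w = RNG.standard_normal((3, 3, 3, 2))
        b = RNG.standard_normal(2)
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.conv(ts[0], ts[1], ts[2])),
                                  target((2, 4, 5, 2))), [x, w, b])

    def test_conv3d_k3(self):
        x = RNG.standard_normal((1, 3, 4, 3, 2))
        w = RNG.standard_normal((3, 3, 3, 2, 2))
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.conv(ts[0], ts[1])),
                                  target((1, 3, 4, 3, 2))), [x, w])

    def test_conv2d_k1(self):
        x = RNG.standard_normal((2, 4, 4, 3))
        w = RNG.standard_normal((1, 1, 3, 2))
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.conv(ts[0], ts[1])),
                                  target((2, 4, 4, 2))), [x, w])

    @pytest.mark.parametrize("rank", [2, 3])
    def test_transposed_conv(self, rank):
        shape = (1,) + (3,) * rank + (2,)
        x = RNG.standard_normal(shape)
        w = RNG.standard_normal((2, (2 ** rank) * 2))
        b = RNG.standard_normal(2)
        out_shape = (1,) + (6,) * rank + (2,)
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.conv_transpose2x(ts[0], ts[1], ts[2])),
                                  target(out_shape)), [x, w, b])

    @pytest.mark.parametrize("rank", [2, 3])
    def test_maxpool(self, rank):
        shape = (2,) + (4,) * rank + (2,)
        x = RNG.standard_normal(shape)
        out_shape = (2,) + (2,) * rank + (2,)
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.maxpool2x(ts[0])), target(out_shape)), [x])

    @pytest.mark.parametrize("training", [True, False])
    def test_batch_norm(self, training):
        x = RNG.standard_normal((2, 3, 3, 2))
        gamma = RNG.standard_normal(2) + 1.5
        beta = RNG.standard_normal(2)

        def loss(ts):
            rm, rv = np.full(2, 0.2), np.full(2, 1.3)
            return T.bce_loss(T.sigmoid(
                T.batch_norm(ts[0], ts[1], ts[2], rm, rv, training)),
                target((2, 3, 3, 2)))

        assert_grads_match(loss, [x, gamma, beta])

    def test_concat_add_relu(self):
        a = RNG.standard_normal((1, 4, 4, 2))
        c = RNG.standard_normal((1, 4, 4, 3))
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.relu(T.concat([ts[0], ts[1]]))),
                                  target((1, 4, 4, 5))), [a, c])

    def test_bias_broadcast_add(self):
        a = RNG.standard_normal((2, 3, 3, 2))
        b = RNG.standard_normal(2)
        assert_grads_match(
            lambda ts: T.bce_loss(T.sigmoid(T.add(ts[0], ts[1])),
                                  target((2, 3, 3, 2))), [a, b])


class TestContracts:
    def test_bce_sum_equals_mean_times_pixels(self):
        p = T.Tensor(RNG.random((2, 8, 8, 1)))
        t = target((2, 8, 8, 1))
        s = float(T.bce_loss(p, t, reduction="sum").data)
        m = float(T.bce_loss(p, t, reduction="mean").data)
        assert s == pytest.approx(m * p.data.size, rel=1e-12)

    def test_maxpool_rejects_odd_extent(self):
        with pytest.raises(ValueError):
            T.maxpool2x(T.Tensor(np.zeros((1, 5, 4, 1))))

    def test_backward_requires_scalar(self):
        x = T.Tensor(np.zeros((2, 2)), requires_grad=True)
        with pytest.raises(ValueError):
            T.add(x, x).backward()

    def test_no_grad_suppresses_tape(self):
        x = T.Tensor(RNG.standard_normal((1, 4, 4, 2)), requires_grad=True)
        w = T.Tensor(RNG.standard_normal((3, 3, 2, 1)), requires_grad=True)
        with T.no_grad():
            out = T.conv(x, w)
        assert not out.requires_grad

    def test_sigmoid_extreme_inputs_stay_in_unit_interval(self):
        x = T.Tensor(np.array([-1e4, -10.0, 0.0, 10.0, 1e4]))
        y = T.sigmoid(x).data
        assert np.all((y >= 0) & (y <= 1))
        assert np.all(np.isfinite(y))

    def test_upsample_inverts_pool_spatial_extents(self):
        x = np.zeros((1, 6, 10, 3))
        pooled = T.maxpool2x(T.Tensor(x))
        w = T.Tensor(np.zeros((3, 4 * 3)))
        up = T.conv_transpose2x(pooled, w)
        assert up.data.shape == x.shape
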