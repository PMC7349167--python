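"""Engine-level checks: layer gradients against finite differences, path
equivalence of the two convolution evaluation strategies, and train/eval mode
semantics."""

import numpy as np
import pytest

from eegstream import nn


def fd_param_check(layer, x, n_probes=8, eps=1e-2, tol=5e-3, floor=2e-3, seed=0):
    """Central-difference check of parameter gradients under L = ||out||^2/2.

    Entries where both estimates sit below ``floor`` are skipped: conv nets in
    float32 leave FD noise there.
    """
    rng = np.random.default_rng(seed)

    def loss():
        out = layer.forward(x, training=True)
        return float((out.astype(np.float64) ** 2).sum() / 2), out

    _, out = loss()
    for p in layer.params():
        p.grad[...] = 0.0
    gx = layer.backward(out.astype(np.float32))
    for p in layer.params():
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            old = p.value[idx]
            p.value[idx] = old + eps
            lp, _ = loss()
            p.value[idx] = old - eps
            lm, _ = loss()
            p.value[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = float(p.grad[idx])
            if max(abs(num), abs(ana)) < floor:
                continue
            assert abs(num - ana) / max(abs(num), abs(ana)) < tol, (
                p.name, idx, num, ana)
    return gx


class TestConv3d:
    @pytest.mark.parametrize(
        "stride,kernel",
        [(1, (3, 3, 3)), (2, (3, 3, 3)), ((2, 1, 1), (7, 1, 1)), ((1, 2, 2), (1, 3, 3))],
    )
    def test_im2col_and_slab_paths_agree(self, stride, kernel):
        rng = np.random.default_rng(0)
        pad = tuple((k - 1) // 2 for k in kernel)
        conv = nn.Conv3d(3, 4, kernel, stride, pad, rng=np.random.default_rng(1))
        x = rng.normal(size=(2, 3, 8, 10, 10)).astype(np.float32)
        g = None
        outs, gxs, gws = [], [], []
        for limit in (nn.Conv3d.IM2COL_LIMIT, 0):
            conv.IM2COL_LIMIT = limit
            out = conv.forward(x, training=True)
            if g is None:
                g = rng.normal(size=out.shape).astype(np.float32)
            conv.weight.grad[...] = 0
            gx = conv.backward(g)
            outs.append(out); gxs.append(gx); gws.append(conv.weight.grad.copy())
        assert np.abs(outs[0] - outs[1]).max() < 1e-5
        assert np.abs(gxs[0] - gxs[1]).max() < 1e-5
        assert np.abs(gws[0] - gws[1]).max() < 1e-4

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv3d(2, 3, (3, 3, 3), 1, (1, 1, 1), bias=True,
                         rng=np.random.default_rng(2))
        x = rng.normal(size=(2, 2, 5, 5, 5)).astype(np.float32)
        fd_param_check(conv, x)

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        conv = nn.Conv3d(2, 2, (3, 1, 1), (2, 1, 1), (1, 0, 0),
                         rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 2, 6, 3, 3)).astype(np.float32)
        out = conv.forward(x, training=True)
        gx = conv.backward(out)
        eps = 1e-2
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            lp = float((conv.forward(xp).astype(np.float64) ** 2).sum() / 2)
            lm = float((conv.forward(xm).astype(np.float64) ** 2).sum() / 2)
            num = (lp - lm) / (2 * eps)
            if max(abs(num), abs(gx[idx])) < 2e-3:
                continue
            assert abs(num - gx[idx]) / max(abs(num), abs(gx[idx])) < 5e-3

    def test_known_1x1x1_convolution(self):
        conv = nn.Conv3d(1, 1, 1, bias=True)
        conv.weight.value[...] = 2.0
        conv.bias.value[...] = 1.0
        x = np.arange(8, dtype=np.float32).reshape(1, 1, 2, 2, 2)
        out = conv.forward(x)
        assert np.allclose(out, 2 * x + 1)

    def test_too_small_input_raises(self):
        conv = nn.Conv3d(1, 1, (7, 3, 3))
        with pytest.raises(ValueError, match="too small"):
            conv.forward(np.zeros((1, 1, 3, 3, 3), dtype=np.float32))


class TestPoolingAndNorm:
    def test_maxpool_forward_known_values(self):
        x = np.zeros((1, 1, 2, 2, 2), dtype=np.float32)
        x[0, 0, 1, 0, 1] = 5.0
        out = nn.MaxPool3d().forward(x)
        assert out.shape == (1, 1, 1, 1, 1)
        assert out[0, 0, 0, 0, 0] == 5.0

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = nn.MaxPool3d()
        x = np.zeros((1, 1, 2, 2, 2), dtype=np.float32)
        x[0, 0, 1, 1, 0] = 3.0
        pool.forward(x, training=True)
        gx = pool.backward(np.full((1, 1, 1, 1, 1), 2.0, dtype=np.float32))
        assert gx[0, 0, 1, 1, 0] == 2.0
        assert gx.sum() == 2.0

    def test_maxpool_drops_odd_trailing(self):
        out = nn.MaxPool3d().forward(np.zeros((1, 1, 5, 5, 5), dtype=np.float32))
        assert out.shape == (1, 1, 2, 2, 2)

    def test_batchnorm_normalizes_in_training(self):
        rng = np.random.default_rng(0)
        bn = nn.BatchNorm3d(3)
        x = rng.normal(2.0, 3.0, size=(4, 3, 4, 4, 4)).astype(np.float32)
        out = bn.forward(x, training=True)
        assert np.abs(out.mean(axis=(0, 2, 3, 4))).max() < 1e-5
        assert np.abs(out.std(axis=(0, 2, 3, 4)) - 1).max() < 1e-3

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(1)
        bn = nn.BatchNorm3d(2)
        for _ in range(200):
            bn.forward(rng.normal(1.0, 2.0, size=(8, 2, 2, 2, 2)).astype(np.float32),
                       training=True)
        x = rng.normal(1.0, 2.0, size=(8, 2, 2, 2, 2)).astype(np.float32)
        out = bn.forward(x, training=False)
        expected = (x - bn.running_mean.reshape(1, 2, 1, 1, 1)) / np.sqrt(
            bn.running_var.reshape(1, 2, 1, 1, 1) + bn.eps
        )
        assert np.abs(out - expected).max() < 1e-5

    def test_batchnorm_param_gradients(self):
        rng = np.random.default_rng(2)
        bn = nn.BatchNorm3d(3)
        bn.gamma.value = rng.normal(1, 0.2, 3).astype(np.float32)
        x = rng.normal(size=(3, 3, 3, 3, 3)).astype(np.float32)
        fd_param_check(bn, x)

    def test_global_avg_pool_round_trip(self):
        gap = nn.GlobalAvgPool3d()
        x = np.arange(16, dtype=np.float32).reshape(1, 2, 2, 2, 2)
        out = gap.forward(x, training=True)
        assert np.allclose(out[0], [x[0, 0].mean(), x[0, 1].mean()])
        gx = gap.backward(np.ones((1, 2), dtype=np.float32))
        assert np.allclose(gx, 1.0 / 8)


class TestDropout:
    def test_inactive_at_eval(self):
        d = nn.Dropout(0.5, np.random.default_rng(0))
        x = np.ones((4, 10), dtype=np.float32)
        assert np.array_equal(d.forward(x, training=False), x)

    def test_inverted_scaling_preserves_mean(self):
        d = nn.Dropout(0.5, np.random.default_rng(0))
        x = np.ones((100, 1000), dtype=np.float32)
        out = d.forward(x, training=True)
        assert abs(out.mean() - 1.0) < 0.01

    def test_keep_one_is_identity_in_training(self):
        d = nn.Dropout(1.0)
        x = np.random.default_rng(0).normal(size=(3, 5)).astype(np.float32)
        assert np.array_equal(d.forward(x, training=True), x)


class TestResidual:
    def test_zero_weight_mapping_is_identity(self):
        """With the residual mapping forced to zero the block passes its
        (non-negative) input through exactly."""
        conv = nn.Conv3d(2, 2, (3, 3, 3), 1, (1, 1, 1))
        conv.weight.value[...] = 0.0
        block = nn.Residual(nn.Sequential(conv))
        x = np.abs(np.random.default_rng(0).normal(size=(2, 2, 4, 4, 4))).astype(np.float32)
        out = block.forward(x)
        assert np.array_equal(out, x)

    def test_projection_shortcut_changes_shape(self):
        main = nn.Sequential(nn.Conv3d(2, 4, (3, 3, 3), 2, (1, 1, 1)))
        short = nn.Sequential(nn.Conv3d(2, 4, 1, 2, 0))
        block = nn.Residual(main, short)
        out = block.forward(np.random.default_rng(0).normal(size=(1, 2, 8, 8, 8)).astype(np.float32))
        assert out.shape == (1, 4, 4, 4, 4)

    def test_gradient_flows_through_both_paths(self):
        main = nn.Sequential(nn.Conv3d(2, 2, 1, rng=np.random.default_rng(1)))
        short = nn.Sequential(nn.Conv3d(2, 2, 1, rng=np.random.default_rng(2)))
        block = nn.Residual(main, short)
        x = np.random.default_rng(3).normal(size=(2, 2, 3, 3, 3)).astype(np.float32)
        out = block.forward(x, training=True)
        for p in block.params():
            p.grad[...] = 0
        block.backward(np.ones_like(out))
        assert all(np.any(p.grad != 0) for p in block.params())


class TestLoss:
    def test_cross_entropy_uniform_logits(self):
        logits = np.zeros((4, 2))
        loss, grad = nn.softmax_cross_entropy(logits, np.array([0, 1, 0, 1]))
        assert np.isclose(loss, np.log(2))
        assert np.allclose(grad.sum(axis=1), 0, atol=1e-7)

    def test_cross_entropy_gradient_direction(self):
        logits = np.array([[2.0, -2.0]])
        _, grad = nn.softmax_cross_entropy(logits, np.array([1]))
        assert grad[0, 1] < 0 < grad[0, 0]


class TestSGD:
    def test_plain_step(self):
        p = nn.Param(np.array([1.0, 2.0]))
        p.grad[...] = np.array([0.5, -0.5])
        nn.SGD([p]).step(0.1)
        assert np.allclose(p.value, [0.95, 2.05])

    def test_momentum_accumulates(self):
        p = nn.Param(np.array([0.0]))
        opt = nn.SGD([p], momentum=0.9)
        for _ in range(2):
            p.grad[...] = np.array([1.0])
            opt.step(0.1)
        # v1 = -0.1, v2 = -0.19 -> x = -0.29
        assert np.isclose(p.value[0], -0.29)
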