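"""Backpropagation exactness against naive reference implementations."""

import numpy as np
import pytest
from scipy.signal import convolve2d, correlate2d

from perfusionkit.nn import (
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    UNet,
    mse_loss,
    soft_dice_loss,
    softmax_cross_entropy,
)
from perfusionkit.nn.layers import DTYPE


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        conv = Conv2d(3, 4, rng)
        x = rng.normal(0, 1, (2, 3, 8, 8)).astype(DTYPE)
        out = conv.forward(x)
        w = conv.weight.value.reshape(3, 3, 3, 4)
        for n in (0, 1):
            for co in range(4):
                ref = sum(
                    correlate2d(x[n, c].astype(np.float64), w[c, :, :, co].astype(np.float64), mode="same")
                    for c in range(3)
                ) + conv.bias.value[co]
                assert np.allclose(out[n, co], ref, atol=1e-5)

    def test_backward_matches_flipped_kernel_convolution(self, rng):
        conv = Conv2d(2, 3, rng)
        x = rng.normal(0, 1, (2, 2, 6, 6)).astype(DTYPE)
        conv.forward(x, train=True)
        g = rng.normal(0, 1, (2, 3, 6, 6)).astype(DTYPE)
        for p in conv.params():
            p.zero_grad()
        dx = conv.backward(g)
        w = conv.weight.value.reshape(2, 3, 3, 3)
        for n in (0, 1):
            for c in (0, 1):
                ref = sum(
                    convolve2d(g[n, co].astype(np.float64), w[c, :, :, co].astype(np.float64), mode="same")
                    for co in range(3)
                )
                assert np.allclose(dx[n, c], ref, atol=1e-5)

    def test_weight_gradient_matches_explicit_sum(self, rng):
        conv = Conv2d(2, 2, rng)
        x = rng.normal(0, 1, (3, 2, 5, 5)).astype(DTYPE)
        conv.forward(x, train=True)
        g = rng.normal(0, 1, (3, 2, 5, 5)).astype(DTYPE)
        for p in conv.params():
            p.zero_grad()
        conv.backward(g)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1))).astype(np.float64)
        gw = conv.weight.grad.reshape(2, 3, 3, 2)
        for c in range(2):
            for ki in range(3):
                for kj in range(3):
                    for co in range(2):
                        ref = np.sum(xp[:, c, ki : ki + 5, kj : kj + 5] * g[:, co].astype(np.float64))
                        assert gw[c, ki, kj, co] == pytest.approx(ref, abs=1e-3)


class TestMaxPool:
    def test_forward_backward_match_naive_loops(self, rng):
        x = rng.normal(0, 1, (2, 3, 6, 6)).astype(DTYPE)
        g = rng.normal(0, 1, (2, 3, 3, 3)).astype(DTYPE)
        mp = MaxPool2d()
        out = mp.forward(x, train=True)
        dx = mp.backward(g)
        for n in range(2):
            for c in range(3):
                for i in range(3):
                    for j in range(3):
                        blk = x[n, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                        assert out[n, c, i, j] == blk.max()
                        k = int(np.argmax(blk.reshape(-1)))
                        assert dx[n, c, 2 * i + k // 2, 2 * j + k % 2] == g[n, c, i, j]
        assert dx.sum() == pytest.approx(g.sum(), abs=1e-4)


class TestBatchNorm:
    def test_train_output_is_normalized_and_backward_matches_formula(self, rng):
        bn = BatchNorm2d(3)
        bn.gamma.value[:] = rng.normal(1, 0.3, 3)
        bn.beta.value[:] = rng.normal(0, 0.3, 3)
        x = rng.normal(2, 3, (4, 3, 5, 5)).astype(DTYPE)
        out = bn.forward(x, train=True)
        xhat = (out - bn.beta.value[None, :, None, None]) / bn.gamma.value[None, :, None, None]
        assert np.allclose(xhat.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        assert np.allclose(xhat.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

        g = rng.normal(0, 1, x.shape).astype(DTYPE)
        for p in bn.params():
            p.zero_grad()
        dx = bn.backward(g.copy())
        x64, g64 = x.astype(np.float64), g.astype(np.float64)
        mu = x64.mean(axis=(0, 2, 3), keepdims=True)
        var = x64.var(axis=(0, 2, 3), keepdims=True)
        s = 1.0 / np.sqrt(var + 1e-5)
        xh = (x64 - mu) * s
        gam = bn.gamma.value.astype(np.float64)[None, :, None, None]
        ref = gam * s * (
            g64
            - g64.mean(axis=(0, 2, 3), keepdims=True)
            - xh * (g64 * xh).mean(axis=(0, 2, 3), keepdims=True)
        )
        assert np.allclose(dx, ref, atol=1e-5)

    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm2d(2, momentum=1.0)  # running stats = last batch stats
        x = rng.normal(5, 2, (8, 2, 4, 4)).astype(DTYPE)
        bn.forward(x, train=True)
        out_eval = bn.forward(x, train=False)
        out_train = bn.forward(x, train=True)
        assert np.allclose(out_eval, out_train, atol=1e-4)


class TestLosses:
    def test_cross_entropy_gradient_is_softmax_minus_onehot(self, rng):
        logits = rng.normal(0, 1, (4, 3)).astype(DTYPE)
        labels = np.array([0, 2, 1, 2])
        loss, grad = softmax_cross_entropy(logits, labels)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        onehot = np.eye(3)[labels]
        assert np.allclose(grad, (p - onehot) / 4, atol=1e-6)
        assert loss == pytest.approx(-np.log(p[np.arange(4), labels]).mean(), abs=1e-6)

    def test_dice_loss_on_hard_masks_is_one_minus_dsc(self, rng):
        from perfusionkit.myo_segment import dsc

        a = (rng.random((1, 1, 16, 16)) > 0.5)
        b = (rng.random((1, 1, 16, 16)) > 0.5)
        logits = np.where(a, 50.0, -50.0).astype(DTYPE)  # saturated sigmoid == hard mask
        loss, _ = soft_dice_loss(logits, b.astype(DTYPE))
        assert loss == pytest.approx(1.0 - dsc(a[0, 0], b[0, 0]), abs=1e-5)

    def test_mse_consistency(self, rng):
        pred = rng.normal(0, 1, (3, 4)).astype(DTYPE)
        target = rng.normal(0, 1, (3, 4)).astype(DTYPE)
        loss, grad = mse_loss(pred, target)
        assert loss == pytest.approx(np.mean((pred - target) ** 2), abs=1e-6)
        assert np.allclose(grad, 2 * (pred - target) / pred.size, atol=1e-6)


class TestUNet:
    def test_gradients_flow_to_every_parameter(self, rng):
        net = UNet(1, 1, base=2, depth=2, rng=rng)
        x = rng.normal(0, 1, (2, 1, 16, 16)).astype(DTYPE)
        y = (rng.random((2, 1, 16, 16)) > 0.5).astype(DTYPE)
        logits = net.forward(x, train=True)
        _, grad = soft_dice_loss(logits, y)
        for p in net.params():
            p.zero_grad()
        net.backward(grad)
        nonzero = sum(1 for p in net.params() if np.any(p.grad != 0))
        assert nonzero >= len(net.params()) - 2  # allow dead-ReLU bias corners
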