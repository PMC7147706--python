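"""Engine-level checks: analytic gradients against central differences, and
exact adjointness of the im2col/col2im pair."""

import numpy as np
import pytest

from dermoseg import nn
from dermoseg.nn.layers import col2im, im2col
from oracles import numeric_gradient


class TestGradients:
    def test_conv2d_stride1(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 2, 5, 5)).astype(np.float32), requires_grad=True)
        conv = nn.Conv2d(2, 3, 3, stride=1, padding=1, rng=rng)
        t = (rng.random((2, 3, 5, 5)) > 0.5).astype(np.float32)

        def loss():
            x2 = nn.Tensor(x.data, requires_grad=True)
            return nn.bce_with_logits(conv(x2), t)

        out = nn.bce_with_logits(conv(x), t)
        out.backward()
        num_x = numeric_gradient(lambda: float(loss().data), x.data)
        assert np.allclose(x.grad, num_x, atol=5e-4)
        gw, gb = conv.weight.grad.copy(), conv.bias.grad.copy()
        conv.weight.grad = conv.bias.grad = None
        num_w = numeric_gradient(lambda: float(loss().data), conv.weight.data)
        num_b = numeric_gradient(lambda: float(loss().data), conv.bias.data)
        assert np.allclose(gw, num_w, atol=5e-4)
        assert np.allclose(gb, num_b, atol=5e-4)

    @pytest.mark.parametrize("kernel,stride,pad", [(3, 2, 1), (1, 2, 0), (1, 1, 0)])
    def test_conv2d_variants(self, rng, kernel, stride, pad):
        x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32), requires_grad=True)
        conv = nn.Conv2d(3, 2, kernel, stride=stride, padding=pad, rng=rng)
        oh = (6 + 2 * pad - kernel) // stride + 1
        t = (rng.random((2, 2, oh, oh)) > 0.5).astype(np.float32)

        def loss():
            x2 = nn.Tensor(x.data, requires_grad=True)
            return nn.bce_with_logits(conv(x2), t)

        nn.bce_with_logits(conv(x), t).backward()
        num_x = numeric_gradient(lambda: float(loss().data), x.data)
        assert np.allclose(x.grad, num_x, atol=5e-4)
        gw = conv.weight.grad.copy()
        conv.weight.grad = None
        num_w = numeric_gradient(lambda: float(loss().data), conv.weight.data)
        assert np.allclose(gw, num_w, atol=5e-4)

    def test_conv_transpose(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32), requires_grad=True)
        up = nn.ConvTranspose2d(3, 2, rng=rng)
        t = (rng.random((2, 2, 8, 8)) > 0.5).astype(np.float32)

        def loss():
            x2 = nn.Tensor(x.data, requires_grad=True)
            return nn.bce_with_logits(up(x2), t)

        nn.bce_with_logits(up(x), t).backward()
        num_x = numeric_gradient(lambda: float(loss().data), x.data)
        assert np.allclose(x.grad, num_x, atol=5e-4)
        gw = up.weight.grad.copy()
        up.weight.grad = None
        num_w = numeric_gradient(lambda: float(loss().data), up.weight.data)
        assert np.allclose(gw, num_w, atol=5e-4)

    def test_batchnorm_train_mode(self, rng):
        x = nn.Tensor(rng.normal(size=(3, 2, 4, 4)).astype(np.float32), requires_grad=True)
        bn = nn.BatchNorm2d(2)
        t = (rng.random((3, 2, 4, 4)) > 0.5).astype(np.float32)

        def loss():
            x2 = nn.Tensor(x.data, requires_grad=True)
            return nn.bce_with_logits(bn(x2), t)

        nn.bce_with_logits(bn(x), t).backward()
        num_x = numeric_gradient(lambda: float(loss().data), x.data)
        assert np.allclose(x.grad, num_x, atol=1e-3)
        gg = bn.gamma.grad.copy()
        bn.gamma.grad = None
        num_g = numeric_gradient(lambda: float(loss().data), bn.gamma.data)
        assert np.allclose(gg, num_g, atol=1e-3)

    def test_maxpool(self, rng):
        # well-separated values so the argmax is stable under the probe eps
        base = rng.permutation(36).astype(np.float32).reshape(1, 1, 6, 6)
        x = nn.Tensor(base.copy(), requires_grad=True)
        pool = nn.MaxPool2d(3, 2, 1)
        t = (rng.random((1, 1, 3, 3)) > 0.5).astype(np.float32)

        def loss():
            x2 = nn.Tensor(x.data, requires_grad=True)
            return nn.bce_with_logits(pool(x2), t)

        nn.bce_with_logits(pool(x), t).backward()
        num_x = numeric_gradient(lambda: float(loss().data), x.data, eps=1e-3)
        assert np.allclose(x.grad, num_x, atol=1e-3)

    def test_residual_concat_composition(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 2, 4, 4)).astype(np.float32), requires_grad=True)
        conv = nn.Conv2d(4, 1, 3, padding=1, rng=rng)
        t = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float32)

        def net(x2):
            branch = nn.relu(x2)
            cat = nn.concat(nn.add(x2, x2), branch)
            return nn.bce_with_logits(conv(cat), t)

        net(x).backward()
        num_x = numeric_gradient(lambda: float(net(nn.Tensor(x.data, requires_grad=True)).data), x.data)
        assert np.allclose(x.grad, num_x, atol=1e-3)


class TestColumns:
    def test_im2col_col2im_adjoint(self, rng):
        """<im2col(x), y> == <x, col2im(y)> exactly (they are adjoint maps)."""
        x = rng.normal(size=(2, 3, 7, 7)).astype(np.float64)
        for k, s in [(3, 1), (3, 2), (2, 2)]:
            oh = (7 - k) // s + 1
            cols = im2col(x, k, k, s, oh, oh)
            y = rng.normal(size=cols.shape)
            lhs = float((cols * y).sum())
            rhs = float((x * col2im(y, x.shape, k, k, s, oh, oh)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestTraining:
    def test_adam_reduces_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            g = 2 * p.data
            p.grad = g
            opt.step()
        assert np.all(np.abs(p.data) < 0.05)

    def test_sigmoid_range_and_stability(self):
        x = nn.Tensor(np.array([-100.0, -1.0, 0.0, 1.0, 100.0], dtype=np.float32))
        y = nn.sigmoid(x).data
        assert np.all((y >= 0) & (y <= 1))
        assert y[0] < 1e-30 and y[-1] == 1.0

    def test_bce_matches_closed_form(self):
        z = nn.Tensor(np.array([0.0, 2.0, -2.0], dtype=np.float32))
        t = np.array([1.0, 1.0, 0.0], dtype=np.float32)
        loss = float(nn.bce_with_logits(z, t).data)
        expected = np.mean([np.log(2), np.log1p(np.exp(-2)), np.log1p(np.exp(-2))])
        assert loss == pytest.approx(expected, rel=1e-6)
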