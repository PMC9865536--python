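import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doaeeg.nn import (
    RSBU,
    Adam,
    BatchNorm,
    Conv1d,
    Dense,
    ELU,
    GlobalAvgPool,
    Param,
    ReLU,
    Sequential,
    ShrinkageModule,
    Sigmoid,
    soft_threshold,
)


# --- soft threshold --------------------------------------------------------


def test_soft_threshold_branches():
    x = np.array([-3.0, -1.0, -0.5, 0.0, 0.5, 1.0, 3.0])
    tau = np.array(1.0)
    y = soft_threshold(x, tau)
    assert np.array_equal(y, np.array([-2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0]))


def test_soft_threshold_negative_tau():
    with pytest.raises(ValueError):
        soft_threshold(np.zeros(3), np.array(-0.1))


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_soft_threshold_nonexpansive(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 3, size=20)
    tau = rng.uniform(0, 2)
    y = soft_threshold(x, np.array(tau))
    assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
    assert np.all(y[np.abs(x) <= tau] == 0)
    # shrinks by exactly tau outside the dead zone
    out = np.abs(x) > tau
    assert np.allclose(np.abs(y[out]), np.abs(x[out]) - tau)
    assert np.array_equal(np.sign(y[out]), np.sign(x[out]))


# --- gradient checks -------------------------------------------------------


def _num_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        up = f()
        arr[i] = old - eps
        dn = f()
        arr[i] = old
        g[i] = (up - dn) / (2 * eps)
        it.iternext()
    return g


def _check_layer(layer, x, tol=1e-6, train=True):
    rng = np.random.default_rng(0)
    w = rng.standard_normal(layer.forward(x.copy(), train).shape)

    def loss():
        return float(np.sum(layer.forward(x, train) * w))

    # input gradient
    layer.forward(x.copy(), train)
    gx = layer.backward(w)
    ngx = _num_grad(loss, x)
    assert np.max(np.abs(gx - ngx)) < tol, f"input grad off by {np.max(np.abs(gx - ngx))}"
    # parameter gradients
    for p in layer.params():
        p.grad[...] = 0.0
    layer.forward(x.copy(), train)
    layer.backward(w)
    for p in layer.params():
        ng = _num_grad(loss, p.value)
        assert np.max(np.abs(p.grad - ng)) < tol, f"param grad off by {np.max(np.abs(p.grad - ng))}"


def test_conv1d_gradients():
    rng = np.random.default_rng(1)
    for stride in (1, 2):
        layer = Conv1d(2, 3, 3, stride=stride, rng=rng)
        _check_layer(layer, rng.standard_normal((2, 2, 7)), tol=1e-5)


def test_batchnorm_gradients():
    rng = np.random.default_rng(2)
    _check_layer(BatchNorm(3), rng.standard_normal((4, 3, 5)), tol=1e-5)
    _check_layer(BatchNorm(3), rng.standard_normal((6, 3)), tol=1e-5)


def test_dense_gradients():
    rng = np.random.default_rng(3)
    _check_layer(Dense(4, 3, rng), rng.standard_normal((5, 4)), tol=1e-5)


def test_activation_gradients():
    rng = np.random.default_rng(4)
    for layer in (ELU(), ReLU(), Sigmoid()):
        _check_layer(layer, rng.standard_normal((3, 4)) + 0.05, tol=1e-5)


def test_gap_gradients():
    rng = np.random.default_rng(5)
    _check_layer(GlobalAvgPool(), rng.standard_normal((2, 3, 6)), tol=1e-6)


def test_shrinkage_module_gradients():
    rng = np.random.default_rng(6)
    layer = ShrinkageModule(3, rng)
    _check_layer(layer, rng.standard_normal((4, 3, 6)), tol=1e-4)


def test_rsbu_gradients():
    rng = np.random.default_rng(7)
    _check_layer(RSBU(2, 3, 3, stride=2, rng=rng), rng.standard_normal((3, 2, 8)), tol=1e-4)
    _check_layer(RSBU(3, 3, 3, stride=1, rng=rng), rng.standard_normal((3, 3, 8)), tol=1e-4)


# --- layer semantics -------------------------------------------------------


def test_batchnorm_normalizes_in_train_mode():
    rng = np.random.default_rng(8)
    bn = BatchNorm(4)
    x = rng.normal(5.0, 3.0, size=(64, 4, 10))
    y = bn.forward(x, train=True)
    assert np.allclose(y.mean(axis=(0, 2)), 0, atol=1e-7)
    assert np.allclose(y.std(axis=(0, 2)), 1, atol=1e-3)


def test_batchnorm_eval_uses_running_stats():
    rng = np.random.default_rng(9)
    bn = BatchNorm(2)
    for _ in range(200):
        bn.forward(rng.normal(2.0, 1.5, size=(32, 2, 8)), train=True)
    y = bn.forward(np.full((4, 2, 8), 2.0), train=False)
    assert np.allclose(y, 0.0, atol=0.2)


def test_shrinkage_threshold_bounds():
    rng = np.random.default_rng(10)
    mod = ShrinkageModule(4, rng)
    x = rng.standard_normal((8, 4, 16))
    a, alpha, tau = mod.thresholds(x, train=False)
    assert np.allclose(a, np.abs(x).mean(axis=2))
    assert np.all((alpha > 0) & (alpha < 1))
    assert np.all(tau >= 0) and np.all(tau <= a)


def test_rsbu_shape_mismatch_error():
    rng = np.random.default_rng(11)
    block = RSBU(2, 3, 3, stride=1, rng=rng)  # convolutional shortcut path
    out = block.forward(rng.standard_normal((2, 2, 8)))
    assert out.shape == (2, 3, 8)


def test_sequential_composition():
    rng = np.random.default_rng(12)
    net = Sequential(Dense(3, 5, rng), ReLU(), Dense(5, 2, rng))
    x = rng.standard_normal((4, 3))
    assert net.forward(x).shape == (4, 2)
    assert len(net.params()) == 4


def test_param_preserves_dtype():
    p = Param(np.ones(3, dtype=np.float32))
    assert p.value.dtype == np.float32
    p2 = Param(np.arange(3))  # integer input is promoted to float
    assert np.issubdtype(p2.value.dtype, np.floating)


def test_adam_minimizes_quadratic():
    p = Param(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        p.grad[...] = 2 * p.value
        opt.step()
    assert np.all(np.abs(p.value) < 1e-2)


def test_adam_weight_decay_only_on_decay_params():
    a = Param(np.array([1.0]), decay=True)
    b = Param(np.array([1.0]), decay=False)
    opt = Adam([a, b], lr=0.01, weight_decay=1.0)
    opt.zero_grad()
    opt.step()
    assert abs(a.value[0]) < 1.0  # decayed toward zero
    assert b.value[0] == 1.0  # untouched (zero gradient, no decay)
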