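import numpy as np
import pytest

from forceseg.nn import (
    Adam,
    BudgetExceededError,
    FeatureMapSet,
    ModelConfig,
    SegmentationModel,
    Tensor,
    build_model,
    count_parameters,
    segment,
)
from forceseg.nn.autograd import get_dtype, set_dtype


@pytest.fixture
def f64():
    set_dtype(np.float64)
    yield
    set_dtype(np.float32)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize(
    "op",
    [
        lambda t: (t * t + 2.0 * t).sum(),
        lambda t: t.sigmoid().sum(),
        lambda t: t.relu().sum(),
        lambda t: (t.exp() / (1.0 + t.exp())).log().sum() * -1.0,
        lambda t: t.softmax(axis=-1).pow(2.0).sum(),
    ],
)
def test_elementwise_gradients(op, f64, rng):
    x = rng.normal(0, 1, (3, 5))
    t = Tensor(x.copy(), requires_grad=True)
    out = op(t)
    out.backward()
    expected = numeric_grad(lambda: float(op(Tensor(t.data)).data), t.data)
    assert np.allclose(t.grad, expected, atol=1e-6)


def test_conv_and_pool_gradients(f64, rng):
    x = rng.normal(0, 1, (2, 3, 8, 8))
    w = rng.normal(0, 1, (4, 3, 3, 3))
    tx = Tensor(x.copy(), requires_grad=True)
    tw = Tensor(w.copy(), requires_grad=True)
    out = tx.conv2d(tw, stride=2, padding=1).sigmoid().sum()
    out.backward()

    def f():
        return float(
            Tensor(tx.data).conv2d(Tensor(tw.data), stride=2, padding=1)
            .sigmoid().sum().data
        )

    assert np.allclose(tx.grad, numeric_grad(f, tx.data), atol=1e-5)
    assert np.allclose(tw.grad, numeric_grad(f, tw.data), atol=1e-5)

    tp = Tensor(x.copy(), requires_grad=True)
    (tp.minpool3() * Tensor(rng.normal(0, 1, (2, 3, 8, 8)))).sum().backward()
    assert tp.grad is not None and tp.grad.shape == x.shape


def test_bilinear_resize_gradient(f64, rng):
    x = rng.normal(0, 1, (1, 2, 4, 4))
    t = Tensor(x.copy(), requires_grad=True)
    t.bilinear_resize(7, 7).pow(2.0).sum().backward()

    def f():
        return float(Tensor(t.data).bilinear_resize(7, 7).pow(2.0).sum().data)

    assert np.allclose(t.grad, numeric_grad(f, t.data), atol=1e-5)


def test_parameter_budget_default_model():
    model = build_model()
    assert count_parameters(model) <= 5_200_000


def test_budget_enforced():
    with pytest.raises(BudgetExceededError):
        build_model(ModelConfig(param_budget=10))


def test_forward_shapes_and_range():
    model = build_model(ModelConfig.ablation_scale(), seed=0)
    model.eval()
    x = Tensor(np.random.default_rng(0).random((2, 3, 64, 64)))
    y = model(x)
    assert y.shape == (2, 64, 64)
    assert y.data.min() >= 0.0 and y.data.max() <= 1.0


def test_force_channels_change_output():
    model = build_model(ModelConfig.ablation_scale(use_force_channels=True), seed=0)
    model.eval()
    x = Tensor(np.random.default_rng(1).random((1, 3, 64, 64)))
    base = model(x).data
    force = np.zeros((1, 2, 64, 64))
    force[:, 0, 20:40, 20:40] = 1.0
    forced = model(x, force=force).data
    assert not np.allclose(base, forced)


def test_attention_rows_are_stochastic():
    model = build_model(ModelConfig.ablation_scale(), seed=0)
    model.eval()
    x = Tensor(np.random.default_rng(2).random((1, 3, 64, 64)))
    _, features = model.encode(x)
    agg = model.aggregator(features)
    attn = model.attention.attention_weights(agg, features.maps[-1])
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-5)
    assert attn.min() >= 0


def test_scale_weights_sum_to_one():
    model = build_model(ModelConfig.ablation_scale(), seed=0)
    w = model.aggregator.scale_weights.normalized
    assert w.shape == (4,)
    assert np.isclose(w.sum(), 1.0)


def test_feature_map_set_validation():
    maps = [Tensor(np.zeros((1, 1, 8, 8))), Tensor(np.zeros((1, 1, 4, 4)))]
    with pytest.raises(ValueError):
        FeatureMapSet(maps, [8, 4])  # not increasing
    with pytest.raises(ValueError):
        FeatureMapSet(maps[:1], [4])  # too few


def test_model_determinism_same_seed():
    a = build_model(ModelConfig.ablation_scale(), seed=3)
    b = build_model(ModelConfig.ablation_scale(), seed=3)
    x = Tensor(np.random.default_rng(4).random((1, 3, 32, 32)))
    a.eval(), b.eval()
    assert np.array_equal(a(x).data, b(x).data)


def test_adam_reduces_quadratic():
    t = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([{"params": [t], "lr": 0.1, "weight_decay": 0.0}])
    for _ in range(200):
        opt.zero_grad()
        (t * t).sum().backward()
        opt.step()
    assert np.abs(t.data).max() < 0.1


def test_segment_two_pass_runs():
    model = build_model(ModelConfig.ablation_scale(), seed=0)
    img = np.random.default_rng(5).integers(0, 256, (64, 64, 3), dtype=np.uint8)
    prob, labels = segment(model, img, two_pass=True, return_instances=True)
    assert prob.shape == (64, 64)
    assert labels.shape == (64, 64)
    assert labels.min() >= 0
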