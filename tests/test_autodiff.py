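"""Gradient correctness of the autodiff engine via central finite differences."""

import numpy as np
import pytest

from gexmol.autodiff import (Tensor, concat, embedding_lookup,
                             masked_cross_entropy, no_grad, pergene_linear,
                             softmax)

RNG = np.random.default_rng(42)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def check_grad(build, x_data, atol=1e-6):
    """build(Tensor) -> scalar Tensor; compares autodiff vs numeric grad."""
    x = Tensor(x_data.copy(), requires_grad=True)
    out = build(x)
    out.backward()

    def f():
        with no_grad():
            return float(build(Tensor(x.data)).data)

    num = numerical_grad(f, x.data)
    assert np.allclose(x.grad, num, atol=atol), \
        f"max err {np.abs(x.grad - num).max():.2e}"


_W = np.linspace(-1, 1, 12).reshape(4, 3)


@pytest.mark.parametrize("build", [
    lambda x: (x @ Tensor(_W)).relu().sum(),
    lambda x: softmax(x, axis=-1).log().mean(),
    lambda x: ((x * x).mean(axis=0, keepdims=True) + x).sum(),
    lambda x: (x.swapaxes(0, 1) ** 2.0).sum(),
    lambda x: (x.exp() / (x.exp().sum(axis=-1, keepdims=True))).sum(),
    lambda x: concat([x, x * 2.0], axis=1).sum(),
], ids=["matmul-relu", "softmax-log", "mean-broadcast", "transpose-pow",
        "manual-softmax", "concat"])
def test_composite_gradients(build):
    check_grad(build, RNG.normal(size=(5, 4)) + 0.1)


def test_broadcast_add_mul_gradients():
    b = Tensor(RNG.normal(size=(1, 4)), requires_grad=True)
    x = np.abs(RNG.normal(size=(3, 4))) + 0.5

    def build(t):
        return (Tensor(x) * t + t).sum()

    out = build(b)
    out.backward()

    def f():
        with no_grad():
            return float(build(Tensor(b.data)).data)

    assert np.allclose(b.grad, numerical_grad(f, b.data), atol=1e-6)


def test_embedding_lookup_accumulates_duplicates():
    table = Tensor(RNG.normal(size=(6, 3)), requires_grad=True)
    idx = np.array([[0, 2, 2], [5, 0, 2]])
    out = embedding_lookup(table, idx)
    out.backward(np.ones(out.shape))
    # row 2 appears three times, row 0 twice, row 5 once
    assert np.allclose(table.grad[2], 3.0)
    assert np.allclose(table.grad[0], 2.0)
    assert np.allclose(table.grad[5], 1.0)
    assert np.allclose(table.grad[1], 0.0)


def test_pergene_linear_matches_loop():
    x = Tensor(RNG.normal(size=(2, 4, 3)), requires_grad=True)
    w = Tensor(RNG.normal(size=(4, 3, 5)), requires_grad=True)
    b = Tensor(RNG.normal(size=(4, 5)), requires_grad=True)
    out = pergene_linear(x, w, b)
    expected = np.stack([
        np.stack([x.data[s, g] @ w.data[g] + b.data[g] for g in range(4)])
        for s in range(2)])
    assert np.allclose(out.data, expected)
    out.sum().backward()

    def f():
        with no_grad():
            return float(pergene_linear(Tensor(x.data), Tensor(w.data),
                                        Tensor(b.data)).sum().data)

    assert np.allclose(w.grad, numerical_grad(f, w.data), atol=1e-6)


def test_masked_cross_entropy_value_and_grad():
    logits_data = RNG.normal(size=(2, 3, 5))
    targets = np.array([[1, 4, 0], [2, 2, 3]])
    mask = np.array([[1, 1, 0], [1, 0, 0]], dtype=bool)
    logits = Tensor(logits_data.copy(), requires_grad=True)
    loss = masked_cross_entropy(logits, targets, mask)
    # independent scalar computation
    ref = 0.0
    for b, l in zip(*np.nonzero(mask)):
        z = logits_data[b, l]
        ref += -(z[targets[b, l]] - np.log(np.exp(z - z.max()).sum()) - z.max())
    ref /= mask.sum()
    assert np.isclose(float(loss.data), ref)
    loss.backward()

    def f():
        with no_grad():
            return float(masked_cross_entropy(Tensor(logits.data), targets,
                                              mask).data)

    assert np.allclose(logits.grad, numerical_grad(f, logits.data), atol=1e-6)


def test_no_grad_suppresses_graph():
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = (x * 2.0).sum()
    assert y._backward is None and not y.requires_grad
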