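"""Transformer decoder: contracts, causality, and a straight-line oracle."""

import numpy as np
import pytest

from gexmol.autodiff import Tensor, masked_cross_entropy, no_grad
from gexmol.network import (AttentionRecord, ConditionalMoleculeDecoder,
                            ModelConfig, cell_onehot, reconstruction_loss)
from gexmol.schemes import embed_values, get_scheme

CFG = dict(vocab_size=7, d=4, n_layers=1, n_heads=1, d_ff=8, gene_count=3,
           n_cell_lines=2, scheme="tenfold_binary", max_len=10, dropout=0.0)


def tiny_net(**over):
    cfg = ModelConfig(**{**CFG, **over})
    return ConditionalMoleculeDecoder(cfg, np.random.default_rng(5))


def tiny_inputs(B=2, L=5, seed=0):
    rng = np.random.default_rng(seed)
    tokens = rng.integers(0, CFG["vocab_size"], size=(B, L))
    cells = cell_onehot(["A375"] * B, ("A375", "A549"))
    values = np.round(rng.normal(0, 2, size=(B, CFG["gene_count"])), 1)
    raw = embed_values(values, get_scheme("tenfold_binary"))
    return tokens, cells, raw


# ---------------------------------------------------------------- oracle --

def _ln(x, gamma, beta, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def _lin(x, lin):
    return x @ lin.weight.data + lin.bias.data


def _softmax(z):
    z = z - z.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


def ref_forward(net, tokens, cells, raw):
    """Straight-line numpy re-implementation (single layer, single head)."""
    enc = net.encoder
    vc = _lin(cells, enc.cell_linear)[:, None, :]
    ve = _lin(raw, enc.value_linear)
    g = np.concatenate([vc, ve], axis=1)
    g = _lin(g, enc.shared_linear)
    g = g + _lin(np.maximum(_lin(g, enc.ffn.lin1), 0.0), enc.ffn.lin2)

    B, L = tokens.shape
    x = net.token_emb.weight.data[tokens] + net.positions[:L]
    layer = net.layers[0]
    dk = net.cfg.d // net.cfg.n_heads

    def attn(module, q_in, k_in, v_in, causal):
        q, k, v = (_lin(q_in, module.wq), _lin(k_in, module.wk),
                   _lin(v_in, module.wv))
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk)
        if causal:
            scores = scores + np.triu(np.full(scores.shape[-2:], -1e9), 1)
        w = _softmax(scores)
        return _lin(w @ v, module.wo), w

    h, _ = attn(layer.self_attn, x, x, x, causal=True)
    x = _ln(x + h, layer.ln1.gamma.data, layer.ln1.beta.data)
    h, cross_w = attn(layer.cross_attn, x, g, g, causal=False)
    x = _ln(x + h, layer.ln2.gamma.data, layer.ln2.beta.data)
    h = _lin(np.maximum(_lin(x, layer.ffn.lin1), 0.0), layer.ffn.lin2)
    x = _ln(x + h, layer.ln3.gamma.data, layer.ln3.beta.data)
    return _lin(x, net.out_linear), cross_w


def test_single_layer_matches_straight_line_oracle():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    with no_grad():
        g0 = net.encode_condition(cells, raw)
        logits, cross = net.forward(tokens, g0)
    ref_logits, ref_cross = ref_forward(net, tokens, cells, raw)
    assert np.allclose(logits.data, ref_logits, atol=1e-5)
    assert np.allclose(cross[0, :, 0], ref_cross, atol=1e-5)


# ------------------------------------------------------------- contracts --

def test_output_rows_are_probability_distributions():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    with no_grad():
        probs, _ = net.predict_proba(tokens, net.encode_condition(cells, raw))
    assert np.allclose(probs.sum(-1), 1.0, atol=1e-5)
    assert (probs >= 0).all()


def test_causality_future_tokens_do_not_affect_past_predictions():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs(L=6)
    with no_grad():
        g0 = net.encode_condition(cells, raw)
        p1, _ = net.predict_proba(tokens, g0)
        altered = tokens.copy()
        altered[:, 4:] = 0
        p2, _ = net.predict_proba(altered, g0)
    assert np.allclose(p1[:, :4], p2[:, :4], atol=1e-12)


def test_permuting_gene_rows_of_g0_leaves_output_unchanged():
    """Cross-attention is permutation-invariant over conditioning rows."""
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    with no_grad():
        g0 = net.encode_condition(cells, raw)
        logits, _ = net.forward(tokens, g0)
        perm = np.array([0, 3, 1, 2])  # keep cell row 0, shuffle genes
        g0p = Tensor(g0.data[:, perm, :])
        logits_p, cross_p = net.forward(tokens, g0p)
    assert np.allclose(logits.data, logits_p.data, atol=1e-10)


def test_cross_attention_rows_normalized_every_layer_and_head():
    net = tiny_net(n_layers=3, n_heads=2, d=8)
    tokens, cells, raw = tiny_inputs()
    with no_grad():
        _, cross = net.forward(tokens, net.encode_condition(cells, raw))
    assert cross.shape == (3, 2, 2, 5, 4)  # layers, B, H, L, genes+1
    assert np.allclose(cross.sum(-1), 1.0, atol=1e-6)
    assert (cross >= 0).all()


def test_attention_record_validation():
    w = np.full((1, 1, 2, 4), 0.25)
    AttentionRecord(weights=w, n_tokens=2, gene_count=3)  # fine
    with pytest.raises(ValueError, match="normalized"):
        AttentionRecord(weights=w * 2, n_tokens=2, gene_count=3)
    with pytest.raises(ValueError, match="gene_count"):
        AttentionRecord(weights=w, n_tokens=2, gene_count=5)


def test_shape_validation_errors():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    with pytest.raises(ValueError, match="raw conditioning"):
        net.encode_condition(cells, raw[:, :2, :])
    with no_grad():
        g0 = net.encode_condition(cells, raw)
    with pytest.raises(ValueError, match="vocabulary range"):
        net.forward(tokens + 100, g0)
    with pytest.raises(ValueError, match="max_len"):
        net.forward(np.zeros((2, 99), dtype=int), g0)


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(vocab_size=5, d=6, n_heads=4)
    with pytest.raises(ValueError, match="positive"):
        ModelConfig(vocab_size=0)


# --------------------------------------------------------------- loss ----

def test_loss_of_perfect_predictor_is_zero():
    probs = np.zeros((1, 3, 4))
    targets = np.array([[1, 2, 0]])
    probs[0, np.arange(3), targets[0]] = 1.0
    assert reconstruction_loss(probs, targets) == pytest.approx(0.0, abs=1e-6)


def test_loss_of_uniform_predictor_is_log_vocab():
    V = 11
    probs = np.full((2, 4, V), 1.0 / V)
    targets = np.zeros((2, 4), dtype=int)
    assert reconstruction_loss(probs, targets) == \
        pytest.approx(np.log(V), abs=1e-6)


def test_loss_matches_hand_computed_three_token_example():
    rows = np.array([[[0.7, 0.2, 0.1], [0.1, 0.6, 0.3], [0.25, 0.25, 0.5]]])
    targets = np.array([[0, 1, 2]])
    expected = -(np.log(0.7) + np.log(0.6) + np.log(0.5)) / 3
    assert reconstruction_loss(rows, targets) == pytest.approx(expected)
    # PAD exclusion: mask the last position
    mask = np.array([[1, 1, 0]], dtype=bool)
    expected2 = -(np.log(0.7) + np.log(0.6)) / 2
    assert reconstruction_loss(rows, targets, mask) == pytest.approx(expected2)


def test_training_loss_agrees_with_evaluation_loss():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    g0 = net.encode_condition(cells, raw)
    logits, _ = net.forward(tokens[:, :-1], g0)
    targets = tokens[:, 1:]
    mask = np.ones_like(targets, dtype=bool)
    ce = float(masked_cross_entropy(logits, targets, mask).data)
    probs = _softmax(logits.data)
    assert ce == pytest.approx(reconstruction_loss(probs, targets, mask))


def test_gradients_reach_cell_and_gene_embedding_parameters():
    net = tiny_net()
    tokens, cells, raw = tiny_inputs()
    g0 = net.encode_condition(cells, raw)
    logits, _ = net.forward(tokens[:, :-1], g0)
    loss = masked_cross_entropy(logits, tokens[:, 1:],
                                np.ones_like(tokens[:, 1:], dtype=bool))
    loss.backward()
    assert np.abs(net.encoder.cell_linear.weight.grad).max() > 0
    assert np.abs(net.encoder.value_linear.weight.grad).max() > 0
    assert np.abs(net.token_emb.weight.grad).max() > 0
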