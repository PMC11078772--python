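"""Numeric embedding schemes against an independent bit-twiddling oracle."""

import numpy as np
import pytest

from gexmol.schemes import (decode_raw, embed_value, embed_values,
                            get_scheme, scaled_int)


def oracle_encode(e: float, scheme_name: str, int_buckets: int = 52):
    """Brute-force reference via string binary formatting."""
    sign = [1.0] if e > 0 else [0.0]
    m = int(round(abs(e) * 10))
    if scheme_name == "tenfold_binary":
        bits = [float(c) for c in format(m, "09b")]
        return np.array(sign + bits)
    ip, dd = divmod(m, 10)
    if scheme_name == "binary":
        return np.array(sign + [float(c) for c in format(ip, "05b")]
                        + [float(c) for c in format(dd, "04b")])
    if scheme_name == "one_hot":
        int_oh = [0.0] * int_buckets
        int_oh[ip] = 1.0
        dec_oh = [0.0] * 10
        dec_oh[dd] = 1.0
        return np.array(sign + int_oh + dec_oh)
    raise AssertionError


def grid(max_abs: float) -> np.ndarray:
    steps = int(round(max_abs * 10))
    return np.round(np.arange(-steps, steps + 1) / 10.0, 1)


def test_worked_examples_tenfold_binary():
    s = get_scheme("tenfold_binary")
    assert embed_value(7.3, s).tolist() == [1, 0, 0, 1, 0, 0, 1, 0, 0, 1]
    assert embed_value(-14.4, s).tolist() == [0, 0, 1, 0, 0, 1, 0, 0, 0, 0]


def test_worked_example_binary():
    s = get_scheme("binary")
    assert embed_value(7.3, s).tolist() == [1, 0, 0, 1, 1, 1, 0, 0, 1, 1]


def test_zero_encodes_zero_in_every_scheme():
    for name in ("value", "one_hot", "binary", "tenfold_binary"):
        s = get_scheme(name)
        v = embed_value(0.0, s)
        assert v[0] == 0.0  # sign bit: zero is not positive
        assert decode_raw(v, s) == 0.0


@pytest.mark.parametrize("name", ["one_hot", "binary", "tenfold_binary"])
def test_exhaustive_grid_matches_oracle_and_is_injective(name):
    s = get_scheme(name)
    values = grid(s.max_abs)
    seen = set()
    for e in values:
        v = embed_value(float(e), s)
        assert np.array_equal(v, oracle_encode(float(e), name)), e
        assert v.shape == (s.raw_dim,)
        assert set(np.unique(v)) <= {0.0, 1.0}
        assert decode_raw(v, s) == pytest.approx(float(e))
        seen.add(tuple(v))
    # injective over the grid except +0.0/-0.0 which are one value here
    assert len(seen) == values.size


@pytest.mark.parametrize("name", ["value", "one_hot", "binary",
                                  "tenfold_binary"])
def test_vectorized_embedding_matches_scalar(name):
    s = get_scheme(name)
    hi = s.max_abs if s.max_abs is not None else 51.1
    values = np.round(np.linspace(-hi, hi, 41), 1)
    batch = embed_values(values, s)
    assert batch.shape == (41, s.raw_dim)
    for e, row in zip(values, batch):
        assert np.array_equal(row, embed_value(float(e), s))


def test_sign_rule_boundary():
    s = get_scheme("tenfold_binary")
    assert embed_value(0.1, s)[0] == 1.0
    assert embed_value(-0.1, s)[0] == 0.0
    assert embed_value(0.0, s)[0] == 0.0


def test_half_away_rounding_guard():
    # 14.4 stored as 14.399999... must still scale to 144
    assert scaled_int(14.4) == 144
    assert scaled_int(0.3) == 3
    assert scaled_int(57.0 / 10) == 57


def test_out_of_range_rejected_with_scheme_name():
    s = get_scheme("tenfold_binary")
    with pytest.raises(ValueError, match="tenfold_binary"):
        embed_value(51.2, s)
    with pytest.raises(ValueError, match="binary"):
        embed_value(32.0, get_scheme("binary"))


def test_more_than_one_decimal_rejected():
    with pytest.raises(ValueError, match="fractional"):
        embed_value(7.33, get_scheme("tenfold_binary"))


def test_clip_warns_and_bounds():
    s = get_scheme("tenfold_binary")
    with pytest.warns(UserWarning, match="clipping"):
        out = s.clip(np.array([60.0, -80.0, 1.5]))
    assert out.tolist() == [51.1, -51.1, 1.5]


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown scheme"):
        get_scheme("decimal")
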