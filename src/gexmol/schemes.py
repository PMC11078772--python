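"""Numeric embedding schemes for gene-expression difference values.

Expression differences arrive as signed decimals with exactly one fractional
digit (e.g. 7.3, -14.4).  Four interchangeable raw encodings are supported:

``value``
    the number itself, a length-1 vector.
``one_hot``
    sign bit ++ one-hot over the integer part ++ one-hot over the decimal
    digit (default 52 integer buckets, so raw_dim = 1 + 52 + 10 = 63).
``binary``
    sign bit ++ 5-bit binary of the integer part ++ 4-bit binary of the
    decimal digit (raw_dim = 10; representable magnitude <= 31.9).
``tenfold_binary``
    sign bit ++ 9-bit binary of round(|e| * 10) (raw_dim = 10; representable
    magnitude <= 51.1).  Best performer: it magnifies small expression
    changes instead of burying them in a near-zero float.

The sign bit is 1 for strictly positive values and 0 otherwise (zero is
"not up-regulated").  All bit extraction goes through an exact scaled-integer
path, ``m = round_half_away(|e| * 10)``, so 14.4 always encodes as 144.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

SCHEME_NAMES = ("value", "one_hot", "binary", "tenfold_binary")

#: width of the binary integer / decimal fields
_BINARY_INT_BITS = 5
_BINARY_DEC_BITS = 4
_TENFOLD_BITS = 9


@dataclass(frozen=True)
class EmbeddingScheme:
    """A named raw encoding with its vector width and representable range."""

    name: str
    raw_dim: int
    max_abs: float | None  # None = unbounded (value scheme)
    int_buckets: int = 0   # one_hot only

    def clip(self, values: np.ndarray, warn: bool = True) -> np.ndarray:
        """Clip out-of-range magnitudes to the scheme limit (with a warning)."""
        if self.max_abs is None:
            return np.asarray(values, dtype=float)
        values = np.asarray(values, dtype=float)
        over = np.abs(values) > self.max_abs + 1e-9
        if over.any():
            if warn:
                warnings.warn(
                    f"{int(over.sum())} value(s) exceed the {self.name} "
                    f"representable range +/-{self.max_abs}; clipping",
                    stacklevel=2)
            values = np.clip(values, -self.max_abs, self.max_abs)
        return values


def get_scheme(name: str, onehot_int_buckets: int = 52) -> EmbeddingScheme:
    if name == "value":
        return EmbeddingScheme("value", 1, None)
    if name == "one_hot":
        if onehot_int_buckets < 1:
            raise ValueError("onehot_int_buckets must be >= 1")
        return EmbeddingScheme("one_hot", 1 + onehot_int_buckets + 10,
                               onehot_int_buckets - 1 + 0.9,
                               int_buckets=onehot_int_buckets)
    if name == "binary":
        return EmbeddingScheme("binary", 1 + _BINARY_INT_BITS + _BINARY_DEC_BITS,
                               (2 ** _BINARY_INT_BITS - 1) + 0.9)
    if name == "tenfold_binary":
        return EmbeddingScheme("tenfold_binary", 1 + _TENFOLD_BITS,
                               (2 ** _TENFOLD_BITS - 1) / 10.0)
    raise ValueError(f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}")


def scaled_int(e: float) -> int:
    """|e| * 10 as an exact integer, rounding half away from zero.

    Guards against float residue: 14.4 -> 144, never 143.
    """
    return int(np.floor(abs(e) * 10.0 + 0.5))


def _check_one_decimal(e: float) -> None:
    if abs(e * 10.0 - round(e * 10.0)) > 1e-6:
        raise ValueError(
            f"value {e!r} has more than one fractional digit; expression "
            "differences must be rounded to one decimal place first")


def _check_range(e: float, scheme: EmbeddingScheme) -> None:
    if scheme.max_abs is not None and abs(e) > scheme.max_abs + 1e-9:
        raise ValueError(
            f"|{e}| exceeds the {scheme.name} scheme's representable "
            f"maximum {scheme.max_abs}")


def _bits(n: int, width: int) -> np.ndarray:
    """Big-endian binary of n with fixed width."""
    if n >= 2 ** width:
        raise ValueError(f"{n} does not fit in {width} bits")
    return np.array([(n >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=float)


def embed_value(e: float, scheme: EmbeddingScheme) -> np.ndarray:
    """Raw embedding vector (length scheme.raw_dim) of one difference value."""
    _check_one_decimal(e)
    _check_range(e, scheme)
    if scheme.name == "value":
        return np.array([e], dtype=float)

    sign = 1.0 if e > 0 else 0.0
    m = scaled_int(e)
    int_part, dec_digit = m // 10, m % 10

    if scheme.name == "tenfold_binary":
        return np.concatenate([[sign], _bits(m, _TENFOLD_BITS)])
    if scheme.name == "binary":
        return np.concatenate([[sign],
                               _bits(int_part, _BINARY_INT_BITS),
                               _bits(dec_digit, _BINARY_DEC_BITS)])
    if scheme.name == "one_hot":
        int_oh = np.zeros(scheme.int_buckets)
        int_oh[int_part] = 1.0
        dec_oh = np.zeros(10)
        dec_oh[dec_digit] = 1.0
        return np.concatenate([[sign], int_oh, dec_oh])
    raise AssertionError(scheme.name)


def embed_values(values: np.ndarray, scheme: EmbeddingScheme) -> np.ndarray:
    """Vectorized embed_value over a 1-D or 2-D array -> (..., raw_dim)."""
    values = np.asarray(values, dtype=float)
    flat = values.reshape(-1)
    if np.any(np.abs(flat * 10.0 - np.round(flat * 10.0)) > 1e-6):
        bad = flat[np.abs(flat * 10.0 - np.round(flat * 10.0)) > 1e-6][0]
        raise ValueError(
            f"value {bad!r} has more than one fractional digit")
    if scheme.max_abs is not None and np.any(np.abs(flat) > scheme.max_abs + 1e-9):
        bad = flat[np.abs(flat) > scheme.max_abs + 1e-9][0]
        raise ValueError(
            f"|{bad}| exceeds the {scheme.name} scheme's representable "
            f"maximum {scheme.max_abs}")

    if scheme.name == "value":
        return values[..., None].astype(float)

    sign = (flat > 0).astype(float)[:, None]
    m = np.floor(np.abs(flat) * 10.0 + 0.5).astype(int)
    int_part, dec_digit = m // 10, m % 10

    if scheme.name == "tenfold_binary":
        shifts = _TENFOLD_BITS - 1 - np.arange(_TENFOLD_BITS)
        bits = ((m[:, None] >> shifts) & 1).astype(float)
        out = np.concatenate([sign, bits], axis=1)
    elif scheme.name == "binary":
        si = _BINARY_INT_BITS - 1 - np.arange(_BINARY_INT_BITS)
        sd = _BINARY_DEC_BITS - 1 - np.arange(_BINARY_DEC_BITS)
        out = np.concatenate([sign,
                              ((int_part[:, None] >> si) & 1).astype(float),
                              ((dec_digit[:, None] >> sd) & 1).astype(float)],
                             axis=1)
    else:  # one_hot
        int_oh = np.zeros((flat.size, scheme.int_buckets))
        int_oh[np.arange(flat.size), int_part] = 1.0
        dec_oh = np.zeros((flat.size, 10))
        dec_oh[np.arange(flat.size), dec_digit] = 1.0
        out = np.concatenate([sign, int_oh, dec_oh], axis=1)
    return out.reshape(values.shape + (scheme.raw_dim,))


def decode_raw(vec: np.ndarray, scheme: EmbeddingScheme) -> float:
    """Inverse of embed_value for the discrete schemes (testing/debugging).

    Note the sign bit is 0 for both zero and negative values, so
    decode(encode(-0.0)) == 0.0 is the only collapse on the grid.
    """
    vec = np.asarray(vec, dtype=float)
    if scheme.name == "value":
        return float(vec[0])
    sign = 1.0 if vec[0] > 0.5 else -1.0
    if scheme.name == "tenfold_binary":
        m = int(np.dot(vec[1:], 2 ** (_TENFOLD_BITS - 1 - np.arange(_TENFOLD_BITS))))
    elif scheme.name == "binary":
        ip = int(np.dot(vec[1:1 + _BINARY_INT_BITS],
                        2 ** (_BINARY_INT_BITS - 1 - np.arange(_BINARY_INT_BITS))))
        dd = int(np.dot(vec[1 + _BINARY_INT_BITS:],
                        2 ** (_BINARY_DEC_BITS - 1 - np.arange(_BINARY_DEC_BITS))))
        m = ip * 10 + dd
    else:  # one_hot
        ip = int(np.argmax(vec[1:1 + scheme.int_buckets]))
        dd = int(np.argmax(vec[1 + scheme.int_buckets:]))
        m = ip * 10 + dd
    value = sign * m / 10.0
    return 0.0 if m == 0 else value
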