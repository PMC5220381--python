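"""Desk-scale emulation of the fixed-point datapath.

The hardware evaluates the piecewise-linear gating functions with barrel
shifts and adders only, and factorizes covariances with an integer square
root and an integer divider whose operands are pre-scaled by barrel shifts.
This module reproduces that arithmetic bit-for-bit on integers so the
divergence between the floating-point and fixed-point pipelines can be
bounded and inspected without a synthesizer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .linearize import PiecewiseLinearFunction

__all__ = [
    "FixedPointFormat",
    "quantize",
    "dequantize",
    "fixed_evaluate_plf",
    "fixed_cholesky",
    "FixedPointOverflowWarning",
    "NegativePivotError",
]


class FixedPointOverflowWarning(UserWarning):
    pass


class NegativePivotError(ArithmeticError):
    """A diagonal pivot went non-positive after quantization (hardware failure mode)."""


@dataclass(frozen=True)
class FixedPointFormat:
    """Two's-complement fixed-point format: ``total_bits`` with ``fraction_bits``."""

    total_bits: int = 32
    fraction_bits: int = 16
    signed: bool = True

    def __post_init__(self):
        if not (1 <= self.fraction_bits < self.total_bits):
            raise ValueError("need 1 <= fraction_bits < total_bits")

    @property
    def scale(self) -> int:
        return 1 << self.fraction_bits

    @property
    def max_int(self) -> int:
        return (1 << (self.total_bits - 1)) - 1 if self.signed else (1 << self.total_bits) - 1

    @property
    def min_int(self) -> int:
        return -(1 << (self.total_bits - 1)) if self.signed else 0

    @property
    def resolution(self) -> float:
        return 1.0 / self.scale


def quantize(x: float, fmt: FixedPointFormat, saturate: bool = True) -> int:
    """Round-to-nearest integer representation; saturating on overflow."""
    raw = int(round(float(x) * fmt.scale))
    if raw > fmt.max_int or raw < fmt.min_int:
        if not saturate:
            raise OverflowError(f"{x} not representable in {fmt}")
        warnings.warn(f"value {x} saturated in {fmt.total_bits}-bit format",
                      FixedPointOverflowWarning)
        raw = min(max(raw, fmt.min_int), fmt.max_int)
    return raw


def dequantize(raw: int, fmt: FixedPointFormat) -> float:
    return raw / fmt.scale


def _shift_mul(raw: int, shift: int) -> int:
    """Multiply a fixed-point integer by 2**shift with barrel-shift semantics.

    Right shifts use floor semantics (arithmetic shift), as the hardware does.
    """
    return raw << shift if shift >= 0 else raw >> (-shift)


def fixed_evaluate_plf(plf: PiecewiseLinearFunction, v: float,
                       fmt: FixedPointFormat = FixedPointFormat()) -> float:
    """Evaluate a piecewise-linear function using shifts and adds only.

    The slope multiply ``K_i * V`` is realized as the signed sum of barrel
    shifts stored in the slope's shift-add form; the intercept is a quantized
    constant.  Returns the dequantized result.
    """
    if plf.slope_forms is None:
        raise ValueError("function carries no shift-add slope forms")
    i = int(plf.segment_index(v))
    form = plf.slope_forms[i]
    v_raw = quantize(v, fmt)
    acc = quantize(plf.intercepts[i], fmt)
    for sign, shift in form.terms:
        acc += sign * _shift_mul(v_raw, shift)
    return dequantize(acc, fmt)


def _round_shift(raw: int, shift: int) -> int:
    """Shift right by ``shift`` with round-to-nearest (left shift if negative)."""
    if shift <= 0:
        return raw << (-shift)
    half = 1 << (shift - 1)
    return (raw + half) >> shift


def _int_sqrt_prescaled(raw: int, fmt: FixedPointFormat, prescale_bits: int) -> int:
    """Fixed-point square root via the integer square-root block.

    The integer block only produces ``floor(sqrt(.))``, so the operand is
    enlarged by a barrel shifter: the root emerges at scale ``2**p`` and a
    final rounding shift brings it back to the working scale ``2**f``.  Larger
    ``p`` keeps more true fraction bits of the root (up to the format floor).
    """
    if raw < 0:
        raise NegativePivotError("square root of a negative pivot")
    p = prescale_bits
    f = fmt.fraction_bits
    # raw = v * 2**f;  isqrt(raw << (2p - f)) = floor(sqrt(v) * 2**p)
    shifted = raw << (2 * p - f) if 2 * p >= f else raw >> (f - 2 * p)
    return _round_shift(math.isqrt(shifted), p - f)


def _fixed_div(num: int, den: int, fmt: FixedPointFormat, prescale_bits: int) -> int:
    """Fixed-point division with numerator pre-enlargement.

    ``num`` and ``den`` share the working scale; the numerator is enlarged by
    ``p`` bits so the integer quotient carries scale ``2**p``, then a rounding
    shift restores the working scale.  Small ``p`` truncates fraction bits of
    the quotient, large ``p`` preserves them.
    """
    if den == 0:
        raise ZeroDivisionError("fixed-point division by zero")
    p = prescale_bits
    q = (num << p) // den if (num >= 0) == (den > 0) else -((abs(num) << p) // abs(den))
    return _round_shift(q, p - fmt.fraction_bits)


def fixed_cholesky(p: np.ndarray, fmt: FixedPointFormat = FixedPointFormat(),
                   prescale_bits: int | None = None) -> np.ndarray:
    """Cholesky factor computed with integer sqrt/divide and barrel shifts.

    Implements the Cholesky-Crout recurrence on fixed-point integers; returns
    the dequantized lower-triangular factor.  ``prescale_bits`` defaults to
    ``2 * fraction_bits`` so the integer sqrt/divide retain full fractional
    precision.  Raises :class:`NegativePivotError` when quantization drives a
    pivot non-positive, mirroring the hardware failure mode.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n):
        raise ValueError("matrix must be square")
    if prescale_bits is None:
        prescale_bits = 2 * fmt.fraction_bits
    a = [[quantize(p[i, j], fmt) for j in range(n)] for i in range(n)]
    ell = [[0] * n for _ in range(n)]
    f = fmt.fraction_bits
    for j in range(n):
        # pivot: a_jj - sum_k l_jk^2  (products of two fixed numbers carry
        # scale 2**2f and are brought back by an arithmetic right shift)
        s = a[j][j] - sum(_shift_mul(ell[j][k] * ell[j][k], -f) for k in range(j))
        if s <= 0:
            raise NegativePivotError(f"non-positive pivot at column {j}")
        ell[j][j] = _int_sqrt_prescaled(s, fmt, prescale_bits)
        for i in range(j + 1, n):
            s = a[i][j] - sum(_shift_mul(ell[i][k] * ell[j][k], -f) for k in range(j))
            ell[i][j] = _fixed_div(s, ell[j][j], fmt, prescale_bits)
    return np.array([[dequantize(ell[i][j], fmt) for j in range(n)] for i in range(n)])
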