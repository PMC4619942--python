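"""The 1.4.3.-2 minifloat count codec and its probabilistic increment.

One byte holds a saturating approximate counter: 1 sign bit (the strand flag
of the counting Bloom filter -- *not* an arithmetic sign), 4 exponent bits,
3 mantissa bits, exponent bias -2.  Decoding follows the IEEE-754-inspired
scheme

    e == 0          -> c = t                 (subnormal: exact 0..7)
    1 <= e <= 14    -> c = (1 + t/8) * 2^(e+2) = (8 + t) * 2^(e-1)
    e == 15         -> reserved (never produced; decodes as saturated)

Every integer 0..16 is exactly representable; above that the representable
values thin out geometrically (gap 2^(e-1) within the band of exponent e) up
to the maximum finite value 122,880 at e=14, t=7.  Counters are advanced with
a Morris-style probabilistic increment: advance to the successor with
probability 1/gap, which makes the expected advance exactly 1 per true event
at every state (a martingale), so decoded counts are unbiased estimates of
true counts.

The bit pattern -0 (sign set, magnitude zero) is excluded from arithmetic; it
is reserved as the hash-collision flag of the cascade counter.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "NEG_ZERO",
    "MAX_BYTE",
    "MAX_VALUE",
    "decode",
    "decode_value",
    "encode_exact",
    "gap",
    "successor",
    "prob_increment",
    "representable_values",
    "simulate_counts",
]

SIGN_BIT = 0x80
NEG_ZERO = 0x80  # sign set, magnitude zero: the collision flag
_EXP_MASK = 0x78
_MANT_MASK = 0x07

MAX_BYTE = (14 << 3) | 7  # e=1110, t=111: the largest finite magnitude
MAX_VALUE = (8 + 7) << 13  # = 122,880


def _fields(b: int) -> tuple[int, int, int]:
    return (b >> 7) & 1, (b >> 3) & 0xF, b & 7


def decode_value(b: int) -> float:
    """Decoded count of the magnitude bits (sign ignored).

    The reserved top exponent (e == 15) decodes as +inf ("saturated").
    """
    e = (b >> 3) & 0xF
    t = b & 7
    if e == 0:
        return float(t)
    if e == 15:
        return math.inf
    return float((8 + t) << (e - 1))


def decode(b: int) -> tuple[float, int, bool]:
    """Full decode: (count, strand flag, is_collision).

    ``is_collision`` is True only for the -0 pattern, whose count is 0.
    """
    sign, _e, _t = _fields(b)
    if b == NEG_ZERO:
        return 0.0, sign, True
    return decode_value(b), sign, False


def encode_exact(c: int) -> int | None:
    """Bit pattern (sign 0) exactly representing count ``c``, or None.

    Subnormals cover 0..7; a normalized pattern exists iff
    c = (8 + t) * 2^(e-1) for some t in 0..7, e in 1..14.
    """
    if c < 0:
        raise ValueError("counts are non-negative")
    if c <= 7:
        return c
    for e in range(1, 15):
        q, r = divmod(c, 1 << (e - 1))
        if q < 8:
            return None
        if r == 0 and q <= 15:
            return (e << 3) | (q - 8)
    return None


def representable_values() -> list[int]:
    """All finite representable counts, ascending (0..7 then the bands)."""
    vals = list(range(8))
    for e in range(1, 15):
        vals.extend((8 + t) << (e - 1) for t in range(8))
    return vals


def gap(b: int) -> int:
    """Distance from the decoded magnitude to the next representable value.

    1 through the exact range (e <= 1, i.e. counts 0..15); 2^(e-1) in the
    band of exponent e >= 2 -- including the jump out of the band's top.
    """
    e = (b >> 3) & 0xF
    if e >= 15:
        raise ValueError("reserved exponent has no successor")
    return 1 if e <= 1 else 1 << (e - 1)


def successor(b: int) -> int:
    """Next representable magnitude pattern; raises at the maximum."""
    mag = b & 0x7F
    if mag >= MAX_BYTE:
        raise OverflowError("counter saturated at 122,880")
    t = mag & 7
    if t < 7:
        return mag + 1
    e = (mag >> 3) & 0xF
    # top of a band: (8+7)*2^(e-1) + 2^(e-1) = 8 * 2^e = start of next band
    return ((e + 1) << 3) if e >= 1 else (1 << 3)


def prob_increment(b: int, rng) -> int:
    """Morris-style increment of a counter byte, preserving the sign bit.

    Unit gaps (counts 0..15) advance deterministically; in a band with gap g
    the counter advances with probability 1/g, so the expected advance per
    call is 1 and the decoded count stays unbiased.  Saturates at 122,880.
    ``rng`` needs a ``random()`` method (e.g. :class:`random.Random`).
    """
    sign = b & SIGN_BIT
    mag = b & 0x7F
    if mag >= MAX_BYTE:
        return b
    g = gap(mag)
    if g == 1 or rng.random() * g < 1.0:
        return sign | successor(mag)
    return b


# -- vectorized Monte Carlo ---------------------------------------------------

_VALUE_LUT = np.array([decode_value(m) if (m >> 3) != 15 else np.inf for m in range(128)])
_SUCC_LUT = np.array(
    [successor(m) if m < MAX_BYTE and (m >> 3) != 15 else m for m in range(128)],
    dtype=np.uint8,
)
_GAP_LUT = np.array(
    [gap(m) if (m >> 3) != 15 else 1 for m in range(128)], dtype=np.float64
)


def simulate_counts(true_count: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Decoded values of ``reps`` independent counters after ``true_count``
    probabilistic increments each (vectorized over replicates)."""
    state = np.zeros(reps, dtype=np.uint8)
    for _ in range(true_count):
        movable = state < MAX_BYTE
        advance = movable & (rng.random(reps) * _GAP_LUT[state] < 1.0)
        state[advance] = _SUCC_LUT[state[advance]]
    return _VALUE_LUT[state]
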