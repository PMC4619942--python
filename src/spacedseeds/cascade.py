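"""Two-stage (cascading) counting Bloom filter with minifloat counters.

Stage 1 is the spaced-seed :class:`~spacedseeds.bloom.SeedBloom`: it records
first observations.  When an insert finds all four bits already set the seed
has (apparently) been seen before, and the count cascades to stage 2: a byte
array of 1.4.3.-2 minifloat counters.  Two strand-*sensitive* hash values of
the concatenated seed and its reverse complement pick the byte coordinates
``x`` and ``x'`` on that array; a seed and its reverse complement therefore
address the same unordered pair {x, x'} with the roles swapped.

The update rules (states classified as +0, -0 or nonzero-count):

    (x, x') state      action
    (0,  0 or -0)      x  := count 2, sign 0      first cascade, fwd strand
    (nz, 0 or -0)      increment x, sign kept
    (0 or -0, nz)      increment x', sign := 1    seen on the other strand
    (nz, nz)           both := -0                 hash collision, flagged
    (-0, 0)            x' := count 2, sign := 1
    (-0, -0)           both stay -0

"increment" is the probabilistic minifloat increment; -0 is sticky and marks
a collided byte whose count is no longer trusted; sign 1 ("observed on both
strands") is sticky as well.
"""

from __future__ import annotations

import random
import struct
from pathlib import Path
from typing import NamedTuple

import numpy as np

from spacedseeds import minifloat
from spacedseeds.bloom import SeedBloom
from spacedseeds.seedhash import strand_hash_pair
from spacedseeds.seqcodec import EncodedSeq, SpacedSeed

__all__ = ["CascadeCounter", "classify", "update_rule", "CountResult"]

_CASCADE_MAGIC = b"SSCC"
_VERSION = 1


def classify(byte: int) -> str:
    """State class of a counter byte: 'zero' (+0), 'negzero' (-0) or 'nonzero'."""
    if byte == 0:
        return "zero"
    if byte == minifloat.NEG_ZERO:
        return "negzero"
    return "nonzero"


def update_rule(vx: int, vx2: int, rng) -> tuple[int, int]:
    """Apply the stage-2 update to the byte pair (vx, vx2); return new pair.

    The nine (state x state) cases follow the table in the module docstring.
    """
    cx, cx2 = classify(vx), classify(vx2)
    if cx == "nonzero" and cx2 == "nonzero":
        return minifloat.NEG_ZERO, minifloat.NEG_ZERO
    if cx == "negzero" and cx2 == "negzero":
        return minifloat.NEG_ZERO, minifloat.NEG_ZERO
    if cx == "nonzero":  # (nz, 0|-0): increment x, sign unchanged
        return minifloat.prob_increment(vx, rng), vx2
    if cx2 == "nonzero":  # (0|-0, nz): increment x', set its sign
        return vx, minifloat.SIGN_BIT | minifloat.prob_increment(vx2, rng)
    if cx == "zero":  # (0, 0|-0): first cascade on the forward strand
        return minifloat.encode_exact(2), vx2
    # (-0, 0): x is a flagged collision byte, count on the RC coordinate
    return vx, minifloat.SIGN_BIT | minifloat.encode_exact(2)


class CountResult(NamedTuple):
    estimate: float
    both_strands: bool
    collided: bool


class CascadeCounter:
    """Staged counting Bloom filter: SeedBloom stage 1, minifloat stage 2.

    Parameters
    ----------
    stage1:
        The membership Bloom filter (or an ``m`` to build one).
    m2:
        Stage-2 size in bytes; defaults to stage1.m / 8 (equal memory).
    seed:
        Seed for the probabilistic-increment randomness.
    """

    def __init__(self, stage1: SeedBloom | int, m2: int | None = None, seed: int = 0):
        if isinstance(stage1, int):
            stage1 = SeedBloom(stage1)
        self.stage1 = stage1
        self.m2 = m2 if m2 is not None else max(1, stage1.m // 8)
        self.bytes = np.zeros(self.m2, dtype=np.uint8)
        self._rng = random.Random(seed)

    def _coords(self, S: SpacedSeed | EncodedSeq) -> tuple[int, int]:
        s2k = S.s2k if isinstance(S, SpacedSeed) else S
        hF, hR = strand_hash_pair(s2k)
        return hF % self.m2, hR % self.m2

    def add(self, S: SpacedSeed | EncodedSeq) -> int:
        """Record one observation of a seed; return the stage reached (1 or 2)."""
        pattern = self.stage1.insert(S)
        if not all(pattern):
            return 1
        x, x2 = self._coords(S)
        if x == x2:
            # degenerate coordinate pair (RC palindrome or modulus collision):
            # treat the single byte as the forward coordinate
            vx = int(self.bytes[x])
            if classify(vx) == "zero":
                self.bytes[x] = minifloat.encode_exact(2)
            elif classify(vx) == "nonzero":
                self.bytes[x] = minifloat.prob_increment(vx, self._rng)
            return 2
        new_x, new_x2 = update_rule(int(self.bytes[x]), int(self.bytes[x2]), self._rng)
        self.bytes[x], self.bytes[x2] = new_x, new_x2
        return 2

    def count(self, S: SpacedSeed | EncodedSeq) -> CountResult:
        """Estimated multiplicity of a seed.

        -0 at either coordinate flags a collision; otherwise the estimate is
        the decoded count at whichever coordinate is populated, falling back
        to 1 (stage-1 hit only) or 0 (never seen).
        """
        x, x2 = self._coords(S)
        vx, vx2 = int(self.bytes[x]), int(self.bytes[x2])
        if vx == minifloat.NEG_ZERO or vx2 == minifloat.NEG_ZERO:
            return CountResult(0.0, False, True)
        for v in (vx, vx2):
            if classify(v) == "nonzero":
                value, sign, _ = minifloat.decode(v)
                return CountResult(value, bool(sign), False)
        if self.stage1.contains(S):
            return CountResult(1.0, False, False)
        return CountResult(0.0, False, False)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """SeedBloom header + bits, then a stage-2 header and the byte array."""
        with open(path, "wb") as fh:
            self.stage1.write_to(fh)
            fh.write(_CASCADE_MAGIC)
            fh.write(struct.pack("<HQ", _VERSION, self.m2))
            fh.write(self.bytes.tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "CascadeCounter":
        with open(path, "rb") as fh:
            stage1 = SeedBloom.read_from(fh)
            if fh.read(4) != _CASCADE_MAGIC:
                raise ValueError("missing cascade section")
            version, m2 = struct.unpack("<HQ", fh.read(10))
            if version != _VERSION:
                raise ValueError(f"unsupported version {version}")
            counter = cls(stage1, m2=m2)
            raw = fh.read(m2)
            counter.bytes = np.frombuffer(raw, dtype=np.uint8).copy()
            if counter.bytes.size != m2:
                raise ValueError("truncated byte array")
            return counter

    def dump_tsv(self, seeds, fh) -> None:
        """Emit 'seed<TAB>estimate<TAB>both_strands<TAB>collided' per seed."""
        for S in seeds:
            s2k = S.s2k if isinstance(S, SpacedSeed) else S
            res = self.count(S)
            fh.write(
                f"{s2k.decode()}\t{res.estimate:g}\t"
                f"{int(res.both_strands)}\t{int(res.collided)}\n"
            )
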