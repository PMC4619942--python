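"""Spaced-seed Bloom filter and the associated sizing arithmetic.

A Bloom filter with ``h`` hash functions holding ``n`` elements in ``m`` bits
has (for large ``m``) false positive rate

    f = (1 - exp(-h n / m)) ** h

and the load-optimal hash count is ``h* = (m / n) ln 2``.  Here the four
strand-folded hash values of a seed serve directly as the filter's h = 4 hash
functions, which makes membership automatically strand-canonical: a seed and
its reverse complement map to the same four bit positions.

Positions are ``hash mod m``; ``m`` need not be prime (the avalanche-finalized
hashes are uniform enough).  Because the left/right hash values are folded
single-k-mer hashes, the same bit array supports a degraded single-value
membership probe for a lone k-mer (elevated false positive rate: one hash
instead of four) -- the smaller of the two length scales the assembler can
walk at.
"""

from __future__ import annotations

import math
import struct
from pathlib import Path

import numpy as np

from spacedseeds.seedhash import SEED_SALT, SeedHashes, base_hash, fold, seed_hashes
from spacedseeds.seqcodec import EncodedSeq, SeedTemplate, SpacedSeed

__all__ = ["SeedBloom", "fpr", "optimal_h", "size_for"]

_MAGIC = b"SSBF"
_VERSION = 1


def fpr(h: int, n: int, m: int) -> float:
    """Approximate false positive rate (1 - e^(-hn/m))^h of a Bloom filter."""
    if m <= 0:
        raise ValueError("m must be positive")
    if h < 1:
        raise ValueError("h must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (1.0 - math.exp(-h * n / m)) ** h


def optimal_h(m: int, n: int) -> float:
    """Load-optimal number of hash functions, (m/n) ln 2."""
    if n <= 0:
        raise ValueError("n must be positive")
    return (m / n) * math.log(2.0)


def size_for(n: int, h: int, target_f: float) -> int:
    """Smallest filter size m (bits) with fpr(h, n, m) <= target_f."""
    if not (0.0 < target_f < 1.0):
        raise ValueError("target_f must be in (0, 1)")
    if n == 0:
        return 1
    # invert f = (1 - e^(-hn/m))^h for m, then tighten to the exact integer
    m = max(1, math.ceil(-h * n / math.log(1.0 - target_f ** (1.0 / h))))
    while m > 1 and fpr(h, n, m - 1) <= target_f:
        m -= 1
    while fpr(h, n, m) > target_f:
        m += 1
    return m


class SeedBloom:
    """Bloom filter over spaced seeds keyed by the four folded hash values.

    Parameters
    ----------
    m:
        Filter size in bits.
    template:
        Optional seed geometry, carried for serialization and bookkeeping.
    """

    h = 4  # the folded quadruple *is* the hash family

    def __init__(self, m: int, template: SeedTemplate | None = None):
        if m <= 0:
            raise ValueError("m must be positive")
        self.m = m
        self.template = template
        self.bits = np.zeros((m + 7) // 8, dtype=np.uint8)
        self.n_inserted = 0

    # -- bit primitives ----------------------------------------------------

    def _get(self, pos: int) -> bool:
        return bool(self.bits[pos >> 3] & (1 << (pos & 7)))

    def _set(self, pos: int) -> None:
        self.bits[pos >> 3] |= 1 << (pos & 7)

    def _positions(self, hashes: SeedHashes) -> tuple[int, int, int, int]:
        m = self.m
        return (hashes.xL % m, hashes.xR % m, hashes.xO % m, hashes.xE % m)

    @staticmethod
    def _hashes_of(S: SpacedSeed | EncodedSeq, k: int | None = None) -> SeedHashes:
        if isinstance(S, SpacedSeed):
            return seed_hashes(S.s2k, S.template.k)
        if k is None:
            if len(S) % 2:
                raise ValueError("seed length must be even")
            k = len(S) // 2
        return seed_hashes(S, k)

    # -- public API --------------------------------------------------------

    def insert(self, S: SpacedSeed | EncodedSeq) -> tuple[bool, bool, bool, bool]:
        """Insert a seed; return the pre-insert hit pattern (L, R, O, E).

        An all-True return means every corresponding bit was already set --
        the seed was (apparently) observed before.
        """
        return self.insert_hashes(self._hashes_of(S))

    def insert_hashes(self, hashes: SeedHashes) -> tuple[bool, bool, bool, bool]:
        pat = []
        for pos in self._positions(hashes):
            pat.append(self._get(pos))
            self._set(pos)
        self.n_inserted += 1
        return tuple(pat)

    def query(self, S: SpacedSeed | EncodedSeq) -> tuple[bool, bool, bool, bool]:
        """Per-hash-value membership pattern (L, R, O, E); no mutation."""
        return self.query_hashes(self._hashes_of(S))

    def query_hashes(self, hashes: SeedHashes) -> tuple[bool, bool, bool, bool]:
        return tuple(self._get(pos) for pos in self._positions(hashes))

    def contains(self, S: SpacedSeed | EncodedSeq) -> bool:
        return all(self.query(S))

    def contains_kmer(self, kmer: EncodedSeq) -> bool:
        """Single-hash membership probe of a lone k-mer (two-scale support).

        Checks the one bit the folded k-mer hash maps to.  True for every
        k-mer that ever appeared as the left or right half of an inserted
        seed, with an elevated false positive rate (one hash value, not four).
        """
        return self._get(base_hash(fold(kmer), SEED_SALT) % self.m)

    @property
    def expected_fpr(self) -> float:
        """Analytic false positive rate at the current load."""
        return fpr(self.h, self.n_inserted, self.m)

    # -- serialization -----------------------------------------------------

    def write_to(self, fh) -> None:
        """Write magic, version, k, delta, m, h, n_inserted then the raw bits.

        Header fields are little-endian; k and delta are 0 when no template
        is attached.
        """
        k = self.template.k if self.template else 0
        delta = self.template.delta if self.template else 0
        fh.write(_MAGIC)
        fh.write(struct.pack("<HQQQQQ", _VERSION, k, delta, self.m, self.h, self.n_inserted))
        fh.write(self.bits.tobytes())

    @classmethod
    def read_from(cls, fh) -> "SeedBloom":
        if fh.read(4) != _MAGIC:
            raise ValueError("not a SeedBloom stream")
        version, k, delta, m, h, n_ins = struct.unpack("<HQQQQQ", fh.read(42))
        if version != _VERSION:
            raise ValueError(f"unsupported version {version}")
        if h != cls.h:
            raise ValueError(f"unsupported hash count {h}")
        template = SeedTemplate(k, delta) if k else None
        filt = cls(m, template)
        raw = fh.read((m + 7) // 8)
        filt.bits = np.frombuffer(raw, dtype=np.uint8).copy()
        if filt.bits.size != (m + 7) // 8:
            raise ValueError("truncated bit array")
        filt.n_inserted = n_ins
        return filt

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            self.write_to(fh)

    @classmethod
    def load(cls, path: str | Path) -> "SeedBloom":
        with open(path, "rb") as fh:
            return cls.read_from(fh)
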