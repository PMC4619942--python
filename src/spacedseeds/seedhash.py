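"""Strand-folded hash values for spaced seeds.

For a seed string ``S`` of length 2k the four hash values are

    xL = H{ fold(S(1:1:k))   }      left k-mer
    xR = H{ fold(S(k+1:1:2k)) }     right k-mer
    xO = H{ fold(S(1:2:2k-1)) }     odd positions of the concatenation
    xE = H{ fold(S(2:2:2k))  }      even positions of the concatenation

where ``fold(x)`` is the XOR of the 2-bit packing of ``x`` with that of its
reverse complement (the substring is taken *before* reverse complementation).
The fold makes each hash input identical for a sequence and its reverse
complement, so inserting a seed and querying its reverse complement touch the
same four Bloom-filter bits; under reverse complementation the left/right pair
and the odd/even pair each swap, i.e.

    seed_hashes(revcomp(S)) == (xR, xL, xE, xO).

``H`` is a salted 64-bit FNV-1a accumulation followed by a splitmix64-style
avalanche finalizer -- fixed and documented so hash values are identical
across platforms.  Known limitation: the XOR fold maps every reverse-complement
palindromic string to the all-zero input; odd ``k`` sidesteps this for the
left/right k-mers (no odd-length string is its own reverse complement).
"""

from __future__ import annotations

from typing import NamedTuple

from spacedseeds.seqcodec import EncodedSeq, _pack

__all__ = ["SeedHashes", "base_hash", "fold", "seed_hashes", "strand_hash_pair"]

_MASK64 = (1 << 64) - 1
_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3

#: salt used for the four folded (strand-invariant) hash values
SEED_SALT = 0x5EED_5A17
#: distinct salt for the strand-sensitive pair used by the counting stage
STRAND_SALT = 0x57AA_9D5A


class SeedHashes(NamedTuple):
    """The (left, right, odd, even) 64-bit hash quadruple of a seed."""

    xL: int
    xR: int
    xO: int
    xE: int


def _avalanche(h: int) -> int:
    # splitmix64 finalizer: full-width mixing so low bits are usable moduli
    h = ((h ^ (h >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    h = ((h ^ (h >> 27)) * 0x94D049BB133111EB) & _MASK64
    return h ^ (h >> 31)


def base_hash(data: bytes, salt: int = 0) -> int:
    """Salted 64-bit hash of a byte string (FNV-1a + avalanche finalizer).

    Deterministic and platform-independent; distinct salts give independent
    hash families over the same data.
    """
    h = _FNV_OFFSET ^ _avalanche(salt & _MASK64)
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    # length in the tail separates strings that differ only by zero padding
    h = ((h ^ (len(data) & 0xFF)) * _FNV_PRIME) & _MASK64
    return _avalanche(h)


def fold(x: EncodedSeq) -> bytes:
    """XOR of the 2-bit packing of ``x`` with that of ``revcomp(x)``.

    Identical for a sequence and its reverse complement; all-zero for a
    reverse-complement palindrome.
    """
    codes = x.codes
    n = len(codes)
    folded = bytes(codes[i] ^ 3 ^ codes[n - 1 - i] for i in range(n))
    return _pack(folded)


def seed_hashes(s2k: EncodedSeq, k: int) -> SeedHashes:
    """The four strand-folded hash values of a concatenated seed pair."""
    codes = s2k.codes
    if len(codes) != 2 * k:
        raise ValueError(f"s2k length {len(codes)} != 2k = {2 * k}")
    return SeedHashes(
        xL=base_hash(fold(EncodedSeq(codes[:k])), SEED_SALT),
        xR=base_hash(fold(EncodedSeq(codes[k:])), SEED_SALT),
        xO=base_hash(fold(EncodedSeq(codes[0::2])), SEED_SALT),
        xE=base_hash(fold(EncodedSeq(codes[1::2])), SEED_SALT),
    )


def strand_hash_pair(s2k: EncodedSeq) -> tuple[int, int]:
    """Strand-*sensitive* hash pair (hF, hR) for the counting stage.

    hF hashes the un-folded 2-bit packing of ``s2k``, hR that of its reverse
    complement, under a salt distinct from the folded quadruple.  By
    construction ``strand_hash_pair(revcomp(S)) == (hR, hF)``.
    """
    hF = base_hash(s2k.packed(), STRAND_SALT)
    hR = base_hash(s2k.revcomp().packed(), STRAND_SALT)
    return hF, hR
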