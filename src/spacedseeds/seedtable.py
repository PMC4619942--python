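"""Deterministic spaced-seed hash table with a compact fixed-width record layout.

Each record is keyed by the canonical form of the concatenated seed pair and
accounts for the following bit budget, independent of the gap length:

    sequence content          4k bits   (2-bit codes of the 2k seed bases)
    fwd + rev counters        32 bits   (two 15-bit saturating counts,
                                         rounded up to whole shorts)
    one-base extensions       16 bits   (4 bases x 2 directions x 2 seeds)
    bookkeeping flags         16 bits

Storing the seed content plus the doubled extension field instead of the full
(2k + delta)-base window content saves memory exactly when 2(2k + delta)
exceeds 4k + 16, i.e. strictly for every delta > 8 with a tie at delta = 8
(counters and flags are identical in both layouts and cancel out of the
comparison).

Counts saturate at 2^15 - 1 so they always fit their 15 bits and never wrap.
Extension bits live in the canonical frame: an extension observed on the
reverse strand is complemented and mirrored (seed 1 <-> seed 2, 5' <-> 3')
before being recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from spacedseeds.seqcodec import (
    EncodedSeq,
    SeedTemplate,
    SpacedSeed,
    canonical,
    extract_seeds,
)

__all__ = [
    "SeedRecord",
    "SeedTable",
    "bits_per_record",
    "spaced_content_bits",
    "full_content_bits",
    "savings_threshold",
]

COUNT_CAP = (1 << 15) - 1  # 15-bit saturating counters

_DIRS = {"5p": 0, "3p": 1}


def bits_per_record(k: int, delta: int = 0) -> int:
    """Total record size in bits: 4k + 32 + 16 + 16 (independent of delta)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4 * k + 32 + 16 + 16


def spaced_content_bits(k: int) -> int:
    """Sequence + extension cost of the spaced-seed layout: 4k + 16 bits."""
    return 4 * k + 16


def full_content_bits(k: int, delta: int) -> int:
    """Sequence cost of storing the full (2k+delta)-base window: 2 bits/base."""
    return 2 * (2 * k + delta)


def savings_threshold(k: int) -> int:
    """Smallest T such that the spaced layout is strictly smaller for all
    delta > T.  The content comparison 4k + 16 vs 2(2k + delta) gives T = 8
    for every k, with an exact tie at delta = 8."""
    delta = 0
    while spaced_content_bits(k) >= full_content_bits(k, delta):
        delta += 1
    return delta - 1


@dataclass(slots=True)
class SeedRecord:
    """One hash-table entry, stored in the canonical orientation."""

    seq: EncodedSeq
    fwd_count: int = 0
    rev_count: int = 0
    extensions: int = 0  # 16-bit mask, see extension_bit()
    flags: int = 0  # 16 bookkeeping bits (error-removal etc.)

    def bump(self, strand: str) -> None:
        if strand == "forward":
            self.fwd_count = min(COUNT_CAP, self.fwd_count + 1)
        elif strand == "reverse":
            self.rev_count = min(COUNT_CAP, self.rev_count + 1)
        else:
            raise ValueError(f"strand must be forward|reverse, got {strand!r}")


def extension_bit(seed_index: int, direction: str, base_code: int) -> int:
    """Bit position of one extension: seeds 1|2, directions 5p|3p, bases 0..3."""
    if seed_index not in (1, 2):
        raise ValueError("seed_index must be 1 or 2")
    if direction not in _DIRS:
        raise ValueError("direction must be '5p' or '3p'")
    if not 0 <= base_code <= 3:
        raise ValueError("base code must be 0..3")
    return (seed_index - 1) * 8 + _DIRS[direction] * 4 + base_code


def set_extension(record: SeedRecord, seed_index: int, direction: str, base: str) -> SeedRecord:
    """Set one extension-presence bit (idempotent).  ``base`` is A/C/G/T."""
    code = "ACGT".index(base.upper())
    record.extensions |= 1 << extension_bit(seed_index, direction, code)
    return record


class SeedTable:
    """Dictionary of :class:`SeedRecord` keyed by canonical seed content."""

    def __init__(self, template: SeedTemplate):
        self.template = template
        self._records: dict[bytes, SeedRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SeedRecord]:
        return iter(self._records.values())

    def get(self, S: SpacedSeed | EncodedSeq) -> SeedRecord | None:
        s2k = S.s2k if isinstance(S, SpacedSeed) else S
        return self._records.get(canonical(s2k).codes)

    def upsert(self, S: SpacedSeed | EncodedSeq, strand: str = "forward") -> SeedRecord:
        """Insert or update the record for a seed.

        ``strand`` is the strand the observation came from; the counter that
        is bumped additionally accounts for whether the observed orientation
        is the canonical one, so upserting S and revcomp(S) lands on one
        record with one forward and one reverse observation.
        """
        s2k = S.s2k if isinstance(S, SpacedSeed) else S
        canon = canonical(s2k)
        observed_forward = s2k.codes == canon.codes
        if strand == "reverse":
            observed_forward = not observed_forward
        rec = self._records.get(canon.codes)
        if rec is None:
            rec = SeedRecord(seq=canon)
            self._records[canon.codes] = rec
        rec.bump("forward" if observed_forward else "reverse")
        return rec

    def record_extension(
        self, S: SpacedSeed | EncodedSeq, seed_index: int, direction: str, base: str
    ) -> None:
        """Record an extension observed in the *given seed's* frame, mapping
        it into the canonical frame if the seed is stored reverse-complemented."""
        s2k = S.s2k if isinstance(S, SpacedSeed) else S
        canon = canonical(s2k)
        rec = self._records.get(canon.codes)
        if rec is None:
            rec = self.upsert(S)
            rec.fwd_count = rec.rev_count = 0  # extension-only touch
        if s2k.codes != canon.codes:
            seed_index = 3 - seed_index
            direction = "3p" if direction == "5p" else "5p"
            base = "TGCA"["ACGT".index(base.upper())]
        set_extension(rec, seed_index, direction, base)

    def add_read(self, read: str) -> int:
        """Extract, upsert and wire up extensions for every seed of a read.

        Extensions come from the read context: the base before the left
        k-mer, the first and last gap bases, and the base after the right
        k-mer.  Returns the number of seeds processed.
        """
        k, delta, span = self.template.k, self.template.delta, self.template.span
        seeds = extract_seeds(read, self.template)
        for S in seeds:
            self.upsert(S)
            i = S.origin
            ctx = [
                (1, "5p", i - 1),
                (1, "3p", i + k),
                (2, "5p", i + k + delta - 1),
                (2, "3p", i + span),
            ]
            for seed_index, direction, pos in ctx:
                if 0 <= pos < len(read) and read[pos].upper() in "ACGT":
                    self.record_extension(S, seed_index, direction, read[pos])
        return len(seeds)

    def dump_tsv(self, fh) -> None:
        """Emit 'seed  fwd  rev  extensions(hex)  flags(hex)' sorted by seed."""
        for key in sorted(self._records):
            rec = self._records[key]
            fh.write(
                f"{rec.seq.decode()}\t{rec.fwd_count}\t{rec.rev_count}\t"
                f"0x{rec.extensions:04x}\t0x{rec.flags:04x}\n"
            )
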