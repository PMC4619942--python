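"""2-bit DNA encoding, reverse complementation and spaced-seed extraction.

The alphabet is mapped as A=00, C=01, G=10, T=11 so that complementing a base
is a bitwise NOT restricted to two bits (A<->T, C<->G).  Sequences are held as
one code byte per base (values 0..3) for cheap slicing; :meth:`EncodedSeq.packed`
produces the canonical 2-bit packing (most-significant bits first, four bases
per byte, zero-padded in the final byte) that all hashing is defined over, so
hash inputs are byte-reproducible across platforms.

Coordinates on the public interfaces are 0-based half-open; :func:`substride`
alone uses a 1-based inclusive convention, matching the strided-substring
notation the hash definitions are written in.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "EncodedSeq",
    "SeedTemplate",
    "SpacedSeed",
    "encode",
    "revcomp",
    "substride",
    "extract_seeds",
    "canonical",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
]

_BASES = "ACGT"
_INVALID = 0xFF
# str.maketrans-style byte table: ACGT (either case) -> 0..3, all else -> 0xFF
_ENCODE_TABLE = bytes(
    {65: 0, 67: 1, 71: 2, 84: 3, 97: 0, 99: 1, 103: 2, 116: 3}.get(i, _INVALID)
    for i in range(256)
)
_DECODE_TABLE = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")
_COMPLEMENT_TABLE = bytes.maketrans(bytes([0, 1, 2, 3]), bytes([3, 2, 1, 0]))


class InvalidBaseError(ValueError):
    """Raised when a sequence contains a character outside {A, C, G, T}."""


@dataclass(frozen=True, slots=True)
class EncodedSeq:
    """An immutable 2-bit encoded DNA sequence.

    ``codes`` holds one byte per base with values in 0..3 (A,C,G,T).
    """

    codes: bytes

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return self.decode()

    def decode(self) -> str:
        """Return the plain ACGT string."""
        return self.codes.translate(_DECODE_TABLE).decode("ascii")

    def packed(self) -> bytes:
        """2-bit packing, most-significant-first, four bases per byte.

        The final byte is zero-padded in its low bits when the length is not
        a multiple of four.  This is the byte string hashes are computed over.
        """
        return _pack(self.codes)

    def revcomp(self) -> "EncodedSeq":
        return EncodedSeq(self.codes.translate(_COMPLEMENT_TABLE)[::-1])


def _pack(codes: bytes) -> bytes:
    n = len(codes)
    if n == 0:
        return b""
    acc = 0
    for c in codes:
        acc = (acc << 2) | c
    pad = (-n) % 4
    acc <<= 2 * pad
    return acc.to_bytes((n + pad) // 4, "big")


@dataclass(frozen=True, slots=True)
class SeedTemplate:
    """Geometry of a spaced seed: two ``k``-mers separated by ``delta`` bases."""

    k: int
    delta: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @property
    def span(self) -> int:
        """Genomic footprint of one seed window, ``2k + delta`` bases."""
        return 2 * self.k + self.delta

    def n_seeds(self, read_length: int) -> int:
        """Number of seed windows a clean read of the given length yields."""
        return max(0, read_length - self.span + 1)


@dataclass(frozen=True, slots=True)
class SpacedSeed:
    """One extracted spaced seed: the concatenated 2k seed bases, gap dropped.

    ``origin`` is the 0-based offset of the left k-mer's first base in the
    source read or genome.
    """

    s2k: EncodedSeq
    origin: int
    template: SeedTemplate

    def __post_init__(self) -> None:
        if len(self.s2k) != 2 * self.template.k:
            raise ValueError(
                f"s2k length {len(self.s2k)} != 2k = {2 * self.template.k}"
            )


def encode(s: str) -> EncodedSeq:
    """Encode an ACGT string (case-insensitive); rejects any other character."""
    codes = s.encode("ascii").translate(_ENCODE_TABLE)
    if _INVALID in codes:
        pos = codes.index(_INVALID)
        raise InvalidBaseError(f"invalid base {s[pos]!r} at position {pos}")
    return EncodedSeq(codes)


def revcomp(x: EncodedSeq) -> EncodedSeq:
    """Reverse complement; complement of a code is its 2-bit bitwise NOT."""
    return x.revcomp()


def substride(x: EncodedSeq, a: int, b: int, c: int) -> EncodedSeq:
    """Strided substring S(a:b:c): bases a, a+b, a+2b, ... <= c, 1-based inclusive."""
    if not (1 <= a <= c <= len(x)):
        raise IndexError(f"substride bounds 1 <= {a} <= {c} <= {len(x)} violated")
    if b < 1:
        raise ValueError("stride must be >= 1")
    return EncodedSeq(x.codes[a - 1 : c : b])


def canonical(x: EncodedSeq) -> EncodedSeq:
    """The lexicographically smaller of ``x`` and its reverse complement.

    Comparison is in 2-bit code order (A < C < G < T), which collapses the
    two strands of a seed onto one representative.
    """
    rc = x.revcomp()
    return x if x.codes <= rc.codes else rc


def extract_seeds(read: str, template: SeedTemplate) -> list[SpacedSeed]:
    """Extract every spaced seed from a read.

    Windows whose *seed* bases (either k-mer) contain a non-ACGT character are
    skipped; the gap bases are unconstrained because they are never stored.
    Reads shorter than the span yield an empty list.
    """
    codes = read.encode("ascii").translate(_ENCODE_TABLE)
    k, delta, span = template.k, template.delta, template.span
    n = len(codes)
    out: list[SpacedSeed] = []
    if n < span:
        return out
    clean = _INVALID not in codes
    for i in range(n - span + 1):
        left = codes[i : i + k]
        right = codes[i + k + delta : i + span]
        if not clean and (_INVALID in left or _INVALID in right):
            continue
        out.append(SpacedSeed(EncodedSeq(left + right), i, template))
    return out


# ---------------------------------------------------------------------------
# FASTA/FASTQ ingest (gzip-aware).  Sequences are uppercased on the way in.

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a plain or gzipped FASTA file."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) from a plain or gzipped FASTQ file."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: list[tuple[str, str, str]]) -> None:
    with open(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
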