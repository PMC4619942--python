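"""Shared helpers: string-level oracles independent of the package internals."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_str(s: str) -> str:
    """Plain-string reverse complement (independent of the 2-bit codec)."""
    return s.translate(_COMP)[::-1]


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def string_seeds(seq: str, k: int, delta: int) -> list[tuple[int, str]]:
    """Brute-force spaced-seed extraction on plain strings: (origin, s2k)."""
    span = 2 * k + delta
    out = []
    for i in range(len(seq) - span + 1):
        left = seq[i : i + k]
        right = seq[i + k + delta : i + span]
        if set(left + right) <= set("ACGT"):
            out.append((i, left + right))
    return out


def canonical_str(s: str) -> str:
    return min(s, revcomp_str(s))


def kmer_oracle_assemble(reads: list[str], K: int) -> list[str]:
    """Greedy unique-extension assembler on a plain K-mer de Bruijn graph.

    The classical single-scale baseline the spaced-seed assembler is compared
    against: it walks while the extension is unique on both the out- and
    in-side, so it breaks at any repeat of length >= K.
    """
    nxt: dict[str, set[str]] = {}
    prv: dict[str, set[str]] = {}
    kmers: set[str] = set()
    for r in reads:
        for i in range(len(r) - K + 1):
            km = r[i : i + K]
            kmers.add(canonical_str(km))
            if i + K < len(r):
                nxt.setdefault(km, set()).add(r[i + K])
                prv.setdefault(revcomp_str(km), set()).add(revcomp_str(r[i + K]))
            if i > 0:
                prv.setdefault(km, set()).add(r[i - 1])
                nxt.setdefault(revcomp_str(km), set()).add(revcomp_str(r[i - 1]))
    contigs: list[str] = []
    visited: set[str] = set()
    for start in sorted(kmers):
        if start in visited:
            continue
        seq = start
        guard = 0
        while guard < 10**6:
            guard += 1
            s = nxt.get(seq[-K:], set())
            if len(s) != 1:
                break
            b = next(iter(s))
            if len(prv.get(seq[-K:] [1:] + b, set())) > 1:
                break
            if canonical_str(seq[-K:][1:] + b) in visited:
                break
            seq += b
        while guard < 10**6:
            guard += 1
            s = prv.get(seq[:K], set())
            if len(s) != 1:
                break
            b = next(iter(s))
            if len(nxt.get(b + seq[:K][:-1], set())) > 1:
                break
            if canonical_str(b + seq[:K][:-1]) in visited:
                break
            seq = b + seq
        for i in range(len(seq) - K + 1):
            visited.add(canonical_str(seq[i : i + K]))
        contigs.append(seq)
    contigs.sort(key=len, reverse=True)
    kept: list[str] = []
    for c in contigs:
        if any(c in k or revcomp_str(c) in k for k in kept):
            continue
        kept.append(c)
    return kept


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)
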