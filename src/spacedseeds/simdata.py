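"""Synthetic data generation: genomes, reads and count fixtures.

The generator produces the controlled substrates the rest of the package is
tested on: i.i.d. uniform random genomes with repeat families planted at
non-overlapping positions, shotgun reads with uniform starts, random strand
and substitution errors at a configured per-base rate, and replicated
increment streams for counting-concordance experiments.  Everything is driven
by one integer seed and is byte-for-byte reproducible.

The error model is substitution-only (the correction logic is substitution
based); quality strings are constant at the Phred score implied by the
configured error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from spacedseeds import minifloat

__all__ = ["SimConfig", "sim_genome", "sim_reads", "sim_counts", "DEFAULT_COUNT_BINS"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: logarithmic count bins (powers of two plus the top) used for concordance
DEFAULT_COUNT_BINS = tuple(2 ** i for i in range(14)) + (10_000,)
#: replicates per bin
DEFAULT_COUNT_REPS = 10_000


@dataclass(slots=True)
class SimConfig:
    """Parameters of the synthetic world.

    repeat_spec entries are (count, length, divergence): ``count`` copies of
    a ``length``-base master sequence, each copy independently mutated at the
    per-base ``divergence`` rate (0 plants exact duplicates).
    """

    genome_length: int = 5_000
    repeat_spec: list[tuple[int, int, float]] = field(default_factory=list)
    read_length: int = 150
    coverage: float = 30.0
    sub_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_error_rate <= 1.0:
            raise ValueError("sub_error_rate must be in [0, 1]")
        for count, length, divergence in self.repeat_spec:
            if not 0.0 <= divergence <= 1.0:
                raise ValueError("divergence must be in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0.0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(out.size) < rate)
    # substitute with one of the three *other* bases
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size, dtype=np.uint8)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def sim_genome(config: SimConfig) -> str:
    """Uniform random genome with repeat copies planted non-overlapping.

    Raises when the requested repeat copies cannot be packed into the genome.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = _random_bases(rng, L)
    total = sum(count * length for count, length, _ in config.repeat_spec)
    if total > L:
        raise ValueError("repeat copies do not fit in the genome")
    occupied: list[tuple[int, int]] = []
    for count, length, divergence in config.repeat_spec:
        master = _random_bases(rng, length)
        for _ in range(count):
            for _attempt in range(10_000):
                start = int(rng.integers(0, L - length + 1))
                if all(start + length <= a or start >= b for a, b in occupied):
                    break
            else:
                raise ValueError("could not place repeats without overlap")
            occupied.append((start, start + length))
            genome[start : start + length] = _mutate(rng, master, divergence)
    return _to_str(genome)


def sim_reads(genome: str, config: SimConfig) -> list[tuple[str, str, str]]:
    """Shotgun reads as (id, sequence, quality) triples.

    round(coverage * L / read_length) reads, uniform start positions, each on
    a random strand, substitution errors at ``sub_error_rate``; the quality
    string is constant at the Phred score of that rate (capped at Q40).
    """
    rng = np.random.default_rng(config.seed + 1)
    L, rl = len(genome), config.read_length
    if rl > L:
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(config.coverage * L / rl))
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[codes]
    if config.sub_error_rate > 0:
        q = min(40, int(round(-10 * np.log10(config.sub_error_rate))))
    else:
        q = 40
    qual = chr(q + 33) * rl
    reads = []
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        frag = codes[starts[i] : starts[i] + rl]
        if strands[i]:
            frag = 3 - frag[::-1]
        frag = _mutate(rng, frag, config.sub_error_rate)
        reads.append((f"read{i}/{starts[i]}/{'-' if strands[i] else '+'}", _to_str(frag), qual))
    return reads


def sim_counts(
    bins: Sequence[int] = DEFAULT_COUNT_BINS,
    reps: int = DEFAULT_COUNT_REPS,
    seed: int = 0,
) -> list[tuple[int, np.ndarray]]:
    """Replicated minifloat counting streams per logarithmic bin.

    For each true count ``c`` in ``bins``, runs ``reps`` independent counters
    through ``c`` probabilistic increments and returns (c, decoded values).
    Counts within the exact range decode to the truth deterministically.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in bins:
        if reps == 0:
            out.append((c, np.empty(0)))
            continue
        out.append((c, minifloat.simulate_counts(c, reps, rng)))
    return out
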