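"""Genome uniqueness of spaced seeds as a function of the gap length.

Uniqueness is the fraction of genomic seed *positions* whose canonical spaced
seed occurs exactly once genome-wide (both strands collapsed through the
canonical form; the genome is treated as linear).  At delta = 0 this is the
uniqueness of canonical 2k-mers, so the zero column of a curve doubles as a
plain k-mer uniqueness computation.  Widening the gap stretches the seed's
genomic span without growing its storage, and positions inside repeats become
unique as soon as their windows reach asymmetric flanking sequence -- the
effect the assembler's repeat resolution rests on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from spacedseeds.seqcodec import SeedTemplate, canonical, extract_seeds

__all__ = ["UniquenessCurve", "uniqueness", "curve", "write_curves_tsv"]

DEFAULT_KS = (8, 16, 32)
DEFAULT_DELTAS = tuple(range(0, 401, 25))


@dataclass(slots=True)
class UniquenessCurve:
    k: int
    deltas: list[int]
    n_positions: list[int]
    n_unique: list[int]

    @property
    def uniqueness(self) -> list[float]:
        return [
            u / n if n else float("nan")
            for u, n in zip(self.n_unique, self.n_positions)
        ]


def uniqueness(genome: str, k: int, delta: int) -> float:
    """Fraction of seed positions with genome-wide canonical multiplicity 1.

    Exact census via a multiset of canonical seeds over every window of the
    genome.  Windows with non-ACGT seed bases are excluded from both the
    census and the denominator.
    """
    n_pos, n_unique = _census(genome, k, delta)
    if n_pos == 0:
        raise ValueError(f"genome shorter than the seed span {2 * k + delta}")
    return n_unique / n_pos


def _census(genome: str, k: int, delta: int) -> tuple[int, int]:
    template = SeedTemplate(k, delta)
    seeds = extract_seeds(genome.upper(), template)
    keys = [canonical(S.s2k).codes for S in seeds]
    multiplicity = Counter(keys)
    n_unique = sum(1 for key in keys if multiplicity[key] == 1)
    return len(keys), n_unique


def curve(
    genome: str,
    ks: Sequence[int] = DEFAULT_KS,
    deltas: Sequence[int] = DEFAULT_DELTAS,
) -> list[UniquenessCurve]:
    """One uniqueness curve per k over the delta grid (empty grid -> empty)."""
    out = []
    for k in ks:
        c = UniquenessCurve(k, [], [], [])
        for delta in deltas:
            n_pos, n_unique = _census(genome, k, delta)
            c.deltas.append(delta)
            c.n_positions.append(n_pos)
            c.n_unique.append(n_unique)
        out.append(c)
    return out


def write_curves_tsv(curves: Iterable[UniquenessCurve], fh) -> None:
    fh.write("k\tdelta\tn_positions\tn_unique\tuniqueness\n")
    for c in curves:
        for delta, n_pos, n_unique, u in zip(
            c.deltas, c.n_positions, c.n_unique, c.uniqueness
        ):
            fh.write(f"{c.k}\t{delta}\t{n_pos}\t{n_unique}\t{u:.6f}\n")
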