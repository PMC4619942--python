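"""Toy spaced-seed de Bruijn graph assembler with dual wave fronts.

The graph is held implicitly in a spaced-seed Bloom filter: a node is a full
(2k + delta)-base window and an edge is a 1-base shift.  Because a window's
seed includes both the leading and the lagging k-mer, probing the seed of
``window[1:] + b`` simultaneously advances the leading wave front *and*
asserts that the lagging k-mer agrees with the sequence assembled delta + k
bases earlier -- the mechanism that lets spaced seeds walk through exact
repeats shorter than the span that a plain 2k-mer graph cannot resolve.

While the filter is populated, auxiliary data is collected so that assembly
has somewhere to start: the two end windows of every read are candidate blunt
ends (no observed extension on one side), and the second read to cross a
junction with a different next base gets its window recorded as a branch
representative.  A periodic garbage collection re-probes the blunt list
against the (now fuller) filter and drops entries that have grown extensions.

False-positive Bloom hits create spurious branches, but their survival decays
geometrically with length (probability f^L for a false branch of length L),
so trimming dead-end branches shorter than 2k - 1 bases removes essentially
all of them.

The starting window's gap bases are taken from the read that contributed the
auxiliary entry; a lone seed does not determine them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from spacedseeds.bloom import SeedBloom
from spacedseeds.seedhash import seed_hashes
from spacedseeds.seqcodec import (
    EncodedSeq,
    SeedTemplate,
    SpacedSeed,
    canonical,
    encode,
    extract_seeds,
)

__all__ = [
    "AuxSeedInfo",
    "Contig",
    "build_graph",
    "garbage_collect",
    "extend_contig",
    "trim_branches",
    "assemble",
    "false_branch_survival",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp_str(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True, slots=True)
class AuxSeedInfo:
    """Auxiliary record of a notable window: a blunt end or a branch point.

    ``window`` is the full (2k + delta)-base sequence from the contributing
    read; ``direction`` is the side with no observed extension for blunt
    entries ('5p' or '3p'), None for branches.
    """

    window: str
    kind: str  # 'blunt' | 'branch'
    direction: str | None = None


@dataclass(slots=True)
class Contig:
    sequence: str
    provenance: list[str] = field(default_factory=list)  # seed windows used
    terminated_by: str = "blunt-end"  # 'blunt-end' | 'branch' | 'circular'
    left_stop: str = "blunt-end"
    right_stop: str = "blunt-end"

    def __len__(self) -> int:
        return len(self.sequence)


def _window_seed(window: str, template: SeedTemplate) -> EncodedSeq:
    k, delta = template.k, template.delta
    return encode(window[:k] + window[k + delta :])


def _window_in(filt: SeedBloom, window: str, template: SeedTemplate) -> bool:
    return all(filt.query_hashes(seed_hashes(_window_seed(window, template), template.k)))


def build_graph(
    reads: Iterable[str], template: SeedTemplate, m: int = 1 << 22
) -> tuple[SeedBloom, list[AuxSeedInfo]]:
    """Populate a seed Bloom filter from reads and capture auxiliary seeds.

    Every read initially contributes two blunt candidates (its end windows);
    junctions are caught by the second read to cross them with a different
    next base.  Run :func:`garbage_collect` afterwards to discard blunt
    candidates that other reads have since extended.
    """
    span = template.span
    filt = SeedBloom(m, template)
    aux: list[AuxSeedInfo] = []
    # canonical-frame extension registry used only for branch detection
    next_bases: dict[bytes, set[str]] = {}
    prev_bases: dict[bytes, set[str]] = {}

    for read in reads:
        read = read.upper()
        seeds = extract_seeds(read, template)
        if not seeds:
            continue
        for S in seeds:
            filt.insert(S)
            key = canonical(S.s2k).codes
            is_fwd = S.s2k.codes == key
            i = S.origin
            window = read[i : i + span]
            for pos, fwd_reg, rc_reg in (
                (i + span, next_bases, prev_bases),
                (i - 1, prev_bases, next_bases),
            ):
                if not (0 <= pos < len(read)) or read[pos] not in "ACGT":
                    continue
                base = read[pos] if is_fwd else read[pos].translate(_COMP)
                reg = fwd_reg if is_fwd else rc_reg
                seen = reg.setdefault(key, set())
                if base not in seen:
                    seen.add(base)
                    if len(seen) == 2:
                        aux.append(AuxSeedInfo(window, "branch"))
        aux.append(AuxSeedInfo(read[: span], "blunt", "5p"))
        aux.append(AuxSeedInfo(read[-span:], "blunt", "3p"))
    return filt, aux


def garbage_collect(
    aux: list[AuxSeedInfo], filt: SeedBloom, template: SeedTemplate
) -> list[AuxSeedInfo]:
    """Drop blunt entries that now have an extension in the populated filter.

    Branch entries are kept; the pass is idempotent when no new reads have
    been inserted since the last call.
    """
    kept: list[AuxSeedInfo] = []
    for entry in aux:
        if entry.kind != "blunt":
            kept.append(entry)
            continue
        w = entry.window
        if entry.direction == "3p":
            candidates = (w[1:] + b for b in "ACGT")
        else:
            candidates = (b + w[:-1] for b in "ACGT")
        if not any(_window_in(filt, c, template) for c in candidates):
            kept.append(entry)
    return kept


def _extendable(
    filt: SeedBloom, window: str, template: SeedTemplate, side: str, depth: int
) -> bool:
    """Can this window be walked ``depth`` further steps in the filter?

    A false-positive branch survives each extra step only with the square of
    the per-bit hit probability, so a shallow lookahead discards essentially
    all spurious candidates -- the traversal-level form of trimming branches
    shorter than 2k - 1.
    """
    if depth == 0:
        return True
    for b in "ACGT":
        nxt = window[1:] + b if side == "right" else b + window[:-1]
        if _window_in(filt, nxt, template) and _extendable(
            filt, nxt, template, side, depth - 1
        ):
            return True
    return False


def _step(
    filt: SeedBloom,
    context: str,
    template: SeedTemplate,
    side: str,
    two_scale: bool,
    lookahead: int = 2,
) -> tuple[str | None, str | None]:
    """Probe the four 1-base extensions of a (span-1)-context.

    Returns (base, stop_reason): a unique surviving base, or None with the
    reason ('blunt-end' on zero candidates, 'branch' on ambiguity).  When
    several candidates hit, each is asked to survive ``lookahead`` further
    steps; a unique survivor is accepted, anything else stops the contig at
    a branch.  With ``two_scale`` enabled, a zero-candidate full-scale probe
    falls back to the single-hash k-mer scale to bridge coverage dips.
    """
    if side == "right":
        hits = [b for b in "ACGT" if _window_in(filt, context + b, template)]
    else:
        hits = [b for b in "ACGT" if _window_in(filt, b + context, template)]
    if len(hits) == 1:
        return hits[0], None
    if len(hits) > 1:
        if lookahead > 0:
            survivors = [
                b
                for b in hits
                if _extendable(
                    filt,
                    context + b if side == "right" else b + context,
                    template,
                    side,
                    lookahead,
                )
            ]
            if len(survivors) == 1:
                return survivors[0], None
        return None, "branch"
    if two_scale:
        k = template.k
        if side == "right":
            kmers = [(b, context[-(k - 1) :] + b) for b in "ACGT"]
        else:
            kmers = [(b, b + context[: k - 1]) for b in "ACGT"]
        khits = [b for b, km in kmers if filt.contains_kmer(encode(km))]
        if len(khits) == 1:
            return khits[0], None
    return None, "blunt-end"


def extend_contig(
    start: AuxSeedInfo,
    filt: SeedBloom,
    template: SeedTemplate,
    two_scale: bool = False,
    max_length: int = 10_000_000,
) -> Contig:
    """Grow a contig from an auxiliary window in both directions.

    Each rightward step queries the seed of ``seq[-(span-1):] + b``; the
    query's lagging k-mer lies span bases behind the leading front, which is
    exactly the dual-wavefront assertion.  Extension stops at a blunt end
    (no candidate), a branch (several candidates) or when the walk revisits
    its starting window (circular).
    """
    span = template.span
    if len(start.window) != span:
        raise ValueError("auxiliary window length must equal the template span")
    if not _window_in(filt, start.window, template):
        raise KeyError("start window is not present in the structure")
    seq = start.window
    stops = {"left": "blunt-end", "right": "blunt-end"}
    circular = False
    for side in ("right", "left"):
        while len(seq) < max_length:
            context = seq[-(span - 1) :] if side == "right" else seq[: span - 1]
            base, stop = _step(filt, context, template, side, two_scale)
            if base is None:
                stops[side] = stop
                break
            seq = seq + base if side == "right" else base + seq
            window = seq[-span:] if side == "right" else seq[:span]
            if window == start.window or window == _revcomp_str(start.window):
                circular = True
                seq = seq[:-1] if side == "right" else seq[1:]
                break
        if circular:
            break
    if circular:
        terminated = "circular"
    elif "branch" in stops.values():
        terminated = "branch"
    else:
        terminated = "blunt-end"
    return Contig(
        sequence=seq,
        provenance=[start.window],
        terminated_by=terminated,
        left_stop=stops["left"],
        right_stop=stops["right"],
    )


def false_branch_survival(f: float, length: int, n_tests: float) -> float:
    """Bonferroni-style bound on a false branch surviving to a given length:
    f^length multiplied by the number of opportunities tested."""
    return (f ** length) * n_tests


def trim_branches(
    contigs: list[Contig], template: SeedTemplate, min_overhang: int | None = None
) -> list[Contig]:
    """Remove short dead-end contigs (false-positive spurs).

    A contig is kept when the sequence it adds beyond its initiating window
    is at least ``min_overhang`` bases (default 2k - 1) or when it closed a
    circle.  False branches shrink geometrically with length, so this default
    removes essentially all of them while true terminal contigs survive.
    """
    if min_overhang is None:
        min_overhang = 2 * template.k - 1
    span = template.span
    return [
        c
        for c in contigs
        if c.terminated_by == "circular" or len(c.sequence) - span >= min_overhang
    ]


def assemble(
    reads: Iterable[str],
    template: SeedTemplate,
    m: int = 1 << 22,
    two_scale: bool = False,
    trim: int | None = None,
) -> list[Contig]:
    """End-to-end toy assembly: build, garbage-collect, extend, trim, dedup.

    Traversal order is deterministic (auxiliary entries sorted by window), so
    identical input yields identical contigs.  Reverse-complement duplicates
    and contigs contained in a longer contig are collapsed.
    """
    reads = list(reads)
    if not reads:
        return []
    filt, aux = build_graph(reads, template, m=m)
    aux = garbage_collect(aux, filt, template)
    seen_windows: set[str] = set()
    contigs: list[Contig] = []
    for entry in sorted(aux, key=lambda e: (e.window, e.kind)):
        if entry.window in seen_windows:
            continue
        contig = extend_contig(entry, filt, template, two_scale=two_scale)
        span = template.span
        for i in range(len(contig.sequence) - span + 1):
            w = contig.sequence[i : i + span]
            seen_windows.add(w)
            seen_windows.add(_revcomp_str(w))
        contigs.append(contig)
    contigs = trim_branches(contigs, template, min_overhang=trim)
    # collapse RC duplicates and contained contigs
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    kept: list[Contig] = []
    for c in contigs:
        rc = _revcomp_str(c.sequence)
        if any(c.sequence in k.sequence or rc in k.sequence for k in kept):
            continue
        kept.append(c)
    return kept


def write_contigs_fasta(path, contigs: list[Contig]) -> None:
    """FASTA output with id, length and termination cause in the header."""
    with open(path, "wt") as fh:
        for i, c in enumerate(contigs, 1):
            fh.write(f">contig{i} length={len(c.sequence)} terminated_by={c.terminated_by}\n")
            for j in range(0, len(c.sequence), 70):
                fh.write(c.sequence[j : j + 70] + "\n")
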