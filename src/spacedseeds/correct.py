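"""Read error correction from four-hash Bloom filter hit patterns.

A single substitution inside the stored seed bases of a window is confined to
the left or right k-mer *and* to the odd or even positions of the
concatenation.  Querying an erroneous seed against a filter built from clean
sequence therefore leaves a characteristic two-of-four hit pattern -- e.g.
(left hit, right miss, odd hit, even miss) pins the error to an even position
of the right k-mer, a set of only ~k/2 candidate positions.  Substituting
each candidate with each alternative base and re-querying finds the fixes
that restore the all-hit pattern; a fix is committed only when it is unique
(precision over recall) and, when a counter is available, when the corrected
seed has a nonzero count.

Pattern classes:

    (1,1,1,1)                          present    -- update count
    exactly 2 hits, one of {L,R} and
      one of {O,E}                     single-correctable
    exactly 1 hit                      double-flagged -- possibly two errors;
                                       no cheap action, treated as absent
    everything else (0 hits, >=3 hits,
      or the impossible L+R / O+E
      two-hit combinations)            absent     -- insert in the filter

Errors in the gap bases never touch the seed and need no action at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from spacedseeds.bloom import SeedBloom
from spacedseeds.cascade import CascadeCounter
from spacedseeds.seedhash import seed_hashes
from spacedseeds.seqcodec import EncodedSeq, SeedTemplate, SpacedSeed, extract_seeds

__all__ = [
    "classify_pattern",
    "locate_candidates",
    "try_correct",
    "correct_read",
    "CorrectionResult",
    "ReadChange",
]

_SINGLE_PATTERNS = {
    (True, False, True, False),
    (True, False, False, True),
    (False, True, True, False),
    (False, True, False, True),
}


def classify_pattern(pattern: tuple[bool, bool, bool, bool]) -> str:
    """Classify a (L, R, O, E) hit pattern.

    Returns 'present', 'single' (one substitution may restore the seed),
    'double' (exactly one hit: possibly two substitutions) or 'absent'.
    """
    hits = sum(pattern)
    if hits == 4:
        return "present"
    if tuple(pattern) in _SINGLE_PATTERNS:
        return "single"
    if hits == 1:
        return "double"
    return "absent"


def locate_candidates(pattern: tuple[bool, bool, bool, bool], k: int) -> list[int]:
    """Candidate error positions (1-based within s2k) for a single-correctable
    pattern: the intersection of the missed half with the missed parity.

    Candidates always lie inside the stored 2k seed bases, never the gap.
    """
    if classify_pattern(pattern) != "single":
        raise ValueError(f"pattern {pattern} is not single-correctable")
    xL, xR, xO, xE = pattern
    half = range(1, k + 1) if not xL else range(k + 1, 2 * k + 1)
    parity = 1 if not xO else 0  # odd positions are 1-based odd
    return [p for p in half if p % 2 == parity]


@dataclass(slots=True)
class CorrectionResult:
    action: str  # 'present' | 'corrected' | 'inserted' | 'none'
    pattern: tuple[bool, bool, bool, bool]
    seed: SpacedSeed
    position: int | None = None  # 1-based in s2k, when corrected
    from_base: str | None = None
    to_base: str | None = None


def _count_nonzero(counter: CascadeCounter, s2k: EncodedSeq) -> bool:
    res = counter.count(s2k)
    return not res.collided and res.estimate >= 1


def try_correct(
    S: SpacedSeed,
    filt: SeedBloom,
    counter: Optional[CascadeCounter] = None,
) -> CorrectionResult:
    """Apply the per-window correction rules to one seed.

    present -> update the count (when a counter is given); single-correctable
    -> search candidate substitutions for a unique one restoring the all-hit
    pattern (validated against the counter when given) and report it;
    absent/double or an ambiguous search -> insert the seed as new.
    """
    k = S.template.k
    pattern = filt.query(S)
    cls = classify_pattern(pattern)
    if cls == "present":
        if counter is not None:
            counter.add(S)
        return CorrectionResult("present", pattern, S)
    if cls == "single":
        survivors: list[tuple[int, int]] = []  # (position, new code)
        codes = S.s2k.codes
        for pos in locate_candidates(pattern, k):
            old = codes[pos - 1]
            for new in range(4):
                if new == old:
                    continue
                cand = EncodedSeq(codes[: pos - 1] + bytes([new]) + codes[pos:])
                if all(filt.query_hashes(seed_hashes(cand, k))):
                    if counter is None or _count_nonzero(counter, cand):
                        survivors.append((pos, new))
        if len(survivors) == 1:
            pos, new = survivors[0]
            return CorrectionResult(
                "corrected",
                pattern,
                S,
                position=pos,
                from_base="ACGT"[codes[pos - 1]],
                to_base="ACGT"[new],
            )
    # absent, double-flagged, or no unique fix: record the seed as new
    if counter is not None:
        counter.add(S)
    else:
        filt.insert(S)
    return CorrectionResult("inserted", pattern, S)


@dataclass(slots=True)
class ReadChange:
    """One committed substitution: 0-based read position, bases and pattern."""

    position: int
    from_base: str
    to_base: str
    pattern: tuple[bool, bool, bool, bool]


def seed_pos_to_read_pos(pos: int, origin: int, template: SeedTemplate) -> int:
    """Map a 1-based position within s2k to a 0-based read coordinate."""
    if pos <= template.k:
        return origin + pos - 1
    return origin + template.k + template.delta + (pos - template.k - 1)


def correct_read(
    read: str,
    template: SeedTemplate,
    filt: SeedBloom,
    counter: Optional[CascadeCounter] = None,
    quality: Optional[str] = None,
    q_threshold: int = 20,
) -> tuple[str, list[ReadChange]]:
    """Slide the correction rules over every seed window of a read.

    A substitution is committed only when the window proposes a unique fix
    and, if a Phred quality string is supplied, the base being rewritten has
    quality below ``q_threshold`` (high-quality bases are trusted as-is).
    Committed changes take effect immediately, so later windows see the
    corrected sequence.  Reads shorter than the window span are returned
    unchanged.
    """
    span = template.span
    if len(read) < span:
        return read, []
    current = read.upper()
    changes: list[ReadChange] = []
    for origin in range(len(current) - span + 1):
        window_seeds = extract_seeds(current[origin : origin + span], template)
        if not window_seeds:  # an N within the seed bases
            continue
        S = SpacedSeed(window_seeds[0].s2k, origin, template)
        result = try_correct(S, filt, counter)
        if result.action != "corrected":
            continue
        rp = seed_pos_to_read_pos(result.position, origin, template)
        if quality is not None and ord(quality[rp]) - 33 >= q_threshold:
            continue  # trusted base: leave it alone
        current = current[:rp] + result.to_base + current[rp + 1 :]
        changes.append(
            ReadChange(rp, result.from_base, result.to_base, result.pattern)
        )
    return current, changes
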