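"""Hit-pattern error correction: classification, localisation, round trips."""

import random

import numpy as np
import pytest

from conftest import random_dna
from spacedseeds.bloom import SeedBloom
from spacedseeds.correct import (
    classify_pattern,
    correct_read,
    locate_candidates,
    seed_pos_to_read_pos,
    try_correct,
)
from spacedseeds.seqcodec import SeedTemplate, SpacedSeed, encode, extract_seeds

K, DELTA = 25, 20
TEMPLATE = SeedTemplate(K, DELTA)  # span 70


def _genome_filter(genome: str, m=1 << 22) -> SeedBloom:
    filt = SeedBloom(m, TEMPLATE)
    for S in extract_seeds(genome, TEMPLATE):
        filt.insert(S)
    return filt


class TestClassification:
    @pytest.mark.parametrize(
        "pattern,cls",
        [
            ((1, 1, 1, 1), "present"),
            ((1, 0, 1, 0), "single"),
            ((1, 0, 0, 1), "single"),
            ((0, 1, 1, 0), "single"),
            ((0, 1, 0, 1), "single"),
            ((1, 1, 1, 0), "absent"),
            ((0, 1, 1, 1), "absent"),
            ((0, 0, 0, 0), "absent"),
            ((1, 1, 0, 0), "absent"),  # L+R two-hit: impossible for one error
            ((0, 0, 1, 1), "absent"),
            ((1, 0, 0, 0), "double"),
            ((0, 0, 0, 1), "double"),
        ],
    )
    def test_classes(self, pattern, cls):
        assert classify_pattern(tuple(bool(b) for b in pattern)) == cls


class TestLocateCandidates:
    def test_right_even(self):
        # misses on R and E -> even positions of the right k-mer
        got = locate_candidates((True, False, True, False), 8)
        assert got == [10, 12, 14, 16]

    def test_left_odd(self):
        got = locate_candidates((False, True, False, True), 8)
        assert got == [1, 3, 5, 7]

    @pytest.mark.parametrize(
        "pattern",
        [(1, 0, 1, 0), (1, 0, 0, 1), (0, 1, 1, 0), (0, 1, 0, 1)],
    )
    def test_cardinality_and_bounds(self, pattern):
        for k in (4, 5, 8, 25):
            got = locate_candidates(tuple(bool(b) for b in pattern), k)
            assert len(got) in (k // 2, (k + 1) // 2)
            assert all(1 <= p <= 2 * k for p in got)  # inside s2k, never the gap

    def test_rejects_other_patterns(self):
        with pytest.raises(ValueError):
            locate_candidates((True, True, True, True), 8)


class TestTryCorrect:
    def test_present_seed_untouched(self, rng):
        genome = random_dna(rng, 2000)
        filt = _genome_filter(genome)
        S = extract_seeds(genome, TEMPLATE)[10]
        assert try_correct(S, filt).action == "present"

    def test_planted_substitution_recovered(self, rng):
        genome = random_dna(rng, 2000)
        filt = _genome_filter(genome)
        S = extract_seeds(genome, TEMPLATE)[100]
        from spacedseeds.seqcodec import EncodedSeq

        codes = bytearray(S.s2k.codes)
        pos = K + 2  # 0-based in s2k -> 1-based position 28: right half, even
        codes[pos] = (codes[pos] + 1) % 4
        bad = SpacedSeed(EncodedSeq(bytes(codes)), S.origin, TEMPLATE)
        res = try_correct(bad, filt)
        assert res.action == "corrected"
        assert res.position == pos + 1
        assert res.to_base == "ACGT"[S.s2k.codes[pos]]

    def test_foreign_seed_inserted(self, rng):
        genome = random_dna(rng, 2000)
        filt = _genome_filter(genome)
        foreign = SpacedSeed(encode(random_dna(rng, 2 * K)), 0, TEMPLATE)
        res = try_correct(foreign, filt)
        assert res.action == "inserted"
        assert filt.contains(foreign)


class TestCorrectRead:
    def test_error_free_read_unchanged(self, rng):
        genome = random_dna(rng, 3000)
        filt = _genome_filter(genome)
        read = genome[500:650]
        fixed, changes = correct_read(read, TEMPLATE, filt)
        assert fixed == read and changes == []

    def test_short_read_passthrough(self, rng):
        filt = SeedBloom(1 << 16, TEMPLATE)
        read = random_dna(rng, TEMPLATE.span - 1)
        assert correct_read(read, TEMPLATE, filt) == (read, [])

    def test_gap_error_needs_no_seed_action(self, rng):
        """A substitution confined to gap bases leaves every seed intact."""
        genome = random_dna(rng, 300)
        read = genome[:TEMPLATE.span]
        p = K + DELTA // 2  # middle of the gap of the only window
        wrong = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        bad = read[:p] + wrong + read[p + 1 :]
        filt = _genome_filter(genome)
        assert extract_seeds(bad, TEMPLATE)[0].s2k == extract_seeds(read, TEMPLATE)[0].s2k
        fixed, changes = correct_read(bad, TEMPLATE, filt)
        assert changes == []  # pattern is all-hit, nothing to do

    def test_single_substitution_round_trip(self, rng):
        """Recall >= 95% and false-change rate <= 1% per read on simulated
        reads with one planted substitution each."""
        np_rng = np.random.default_rng(11)
        genome = random_dna(rng, 8000)
        filt = _genome_filter(genome)
        n_reads, recalled, false_changes = 150, 0, 0
        for _ in range(n_reads):
            start = int(np_rng.integers(0, len(genome) - 150))
            clean = genome[start : start + 150]
            p = int(np_rng.integers(0, 150))
            wrong = "ACGT"[("ACGT".index(clean[p]) + int(np_rng.integers(1, 4))) % 4]
            bad = clean[:p] + wrong + clean[p + 1 :]
            fixed, changes = correct_read(bad, TEMPLATE, filt)
            recalled += fixed == clean
            false_changes += sum(1 for ch in changes if ch.position != p)
        assert recalled / n_reads >= 0.95
        assert false_changes / n_reads <= 0.01

    def test_quality_gate_blocks_trusted_bases(self, rng):
        genome = random_dna(rng, 2000)
        read = genome[100:250]
        p = 75
        wrong = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        bad = read[:p] + wrong + read[p + 1 :]
        high_q = "I" * len(bad)  # Q40 everywhere: all bases trusted
        fixed, changes = correct_read(bad, TEMPLATE, _genome_filter(genome), quality=high_q)
        assert fixed == bad and changes == []
        low_q = "#" * len(bad)  # Q2 everywhere: corrections allowed
        fixed, changes = correct_read(bad, TEMPLATE, _genome_filter(genome), quality=low_q)
        assert fixed == read


def test_seed_pos_mapping():
    t = SeedTemplate(4, 10)
    assert seed_pos_to_read_pos(1, 0, t) == 0
    assert seed_pos_to_read_pos(4, 0, t) == 3
    assert seed_pos_to_read_pos(5, 0, t) == 14  # first base of the right k-mer
    assert seed_pos_to_read_pos(8, 7, t) == 7 + 17
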