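"""Toy assembler: aux tracking, garbage collection, wavefront extension."""

import pytest

from conftest import kmer_oracle_assemble, random_dna, revcomp_str
from spacedseeds.assemble import (
    AuxSeedInfo,
    Contig,
    assemble,
    build_graph,
    extend_contig,
    false_branch_survival,
    garbage_collect,
    trim_branches,
)
from spacedseeds.seqcodec import SeedTemplate
from spacedseeds.simdata import SimConfig, sim_genome, sim_reads

K, DELTA = 25, 30
TEMPLATE = SeedTemplate(K, DELTA)  # span 80


def _sim(seed, length=5000, repeats=None, coverage=30):
    cfg = SimConfig(
        genome_length=length,
        repeat_spec=repeats or [],
        read_length=150,
        coverage=coverage,
        seed=seed,
    )
    genome = sim_genome(cfg)
    recs = sim_reads(genome, cfg)
    starts = [int(r[0].split("/")[1]) for r in recs]
    covered = genome[min(starts) : max(s + cfg.read_length for s in starts)]
    return genome, covered, [seq for _, seq, _ in recs]


class TestBuildGraph:
    def test_single_read_two_blunt_ends(self, rng):
        read = random_dna(rng, 200)
        filt, aux = build_graph([read], TEMPLATE)
        blunt = [a for a in aux if a.kind == "blunt"]
        assert len(blunt) == 2
        assert {a.direction for a in blunt} == {"5p", "3p"}
        assert blunt[0].window == read[: TEMPLATE.span]
        assert blunt[1].window == read[-TEMPLATE.span :]

    def test_branch_captured_by_second_read(self, rng):
        """Reads A+X and A+Y sharing prefix A: the second read to cross the
        junction is recorded as a branch representative."""
        a = random_dna(rng, 120)
        x = "A" + random_dna(rng, 59)
        y = "C" + random_dna(rng, 59)
        filt, aux = build_graph([a + x, a + y], TEMPLATE)
        assert any(e.kind == "branch" for e in aux)

    def test_empty_and_short_reads(self):
        filt, aux = build_graph(["ACGT"], TEMPLATE)
        assert aux == []


class TestGarbageCollect:
    def test_tiled_reads_leave_two_blunt_ends(self, rng):
        """Overlapping reads tiling a linear sequence: after garbage
        collection only the two terminal windows stay blunt."""
        genome = random_dna(rng, 400)
        reads = [genome[i : i + 150] for i in range(0, 251, 50)]
        filt, aux = build_graph(reads, TEMPLATE)
        kept = garbage_collect(aux, filt, TEMPLATE)
        blunt = [a for a in kept if a.kind == "blunt"]
        assert len(blunt) == 2
        windows = {a.window for a in blunt}
        assert windows == {genome[: TEMPLATE.span], genome[400 - TEMPLATE.span :]}

    def test_empty_and_idempotent(self, rng):
        assert garbage_collect([], None, TEMPLATE) == []
        read = random_dna(rng, 200)
        filt, aux = build_graph([read], TEMPLATE)
        once = garbage_collect(aux, filt, TEMPLATE)
        assert garbage_collect(once, filt, TEMPLATE) == once


class TestExtendContig:
    def test_clean_linear_genome_single_exact_contig(self, rng):
        genome = random_dna(rng, 1500)
        reads = [genome[i : i + 150] for i in range(0, 1351, 50)]
        filt, aux = build_graph(reads, TEMPLATE)
        aux = garbage_collect(aux, filt, TEMPLATE)
        contig = extend_contig(aux[0], filt, TEMPLATE)
        assert contig.sequence in (genome, revcomp_str(genome))
        assert contig.terminated_by == "blunt-end"

    def test_absent_start_rejected(self, rng):
        filt, _ = build_graph([random_dna(rng, 200)], TEMPLATE)
        with pytest.raises(KeyError):
            extend_contig(
                AuxSeedInfo(random_dna(rng, TEMPLATE.span), "blunt", "5p"),
                filt,
                TEMPLATE,
            )

    def test_genuine_branch_terminates(self, rng):
        """Two valid continuations that disagree and cannot be disambiguated
        stop the contig with a branch verdict."""
        a = random_dna(rng, 200)
        x = "A" + random_dna(rng, 119)
        y = "C" + random_dna(rng, 119)
        filt, aux = build_graph([a + x, a + y], TEMPLATE)
        start = AuxSeedInfo(a[: TEMPLATE.span], "blunt", "5p")
        contig = extend_contig(start, filt, TEMPLATE)
        assert contig.right_stop == "branch"
        # the contig runs up to the junction, not beyond
        assert contig.sequence.endswith(a)


class TestTrimBranches:
    def test_short_spur_removed_long_contig_kept(self):
        span = TEMPLATE.span
        spur = Contig(sequence="A" * (span + 1), terminated_by="branch")
        real = Contig(sequence="A" * (span + 2 * K - 1), terminated_by="blunt-end")
        kept = trim_branches([spur, real], TEMPLATE)
        assert kept == [real]

    def test_false_branch_bound(self):
        # survival of a length-10 false branch at f = 6.25%, Bonferroni 3e9
        assert false_branch_survival(0.0625, 10, 3e9) < 0.003

    def test_override(self):
        span = TEMPLATE.span
        spur = Contig(sequence="A" * (span + 1), terminated_by="branch")
        assert trim_branches([spur], TEMPLATE, min_overhang=1) == [spur]


class TestAssembleEndToEnd:
    def test_no_reads_no_contigs(self):
        assert assemble([], TEMPLATE) == []

    def test_clean_genomes_single_exact_contig(self):
        for seed in (0, 1, 2):
            genome, covered, reads = _sim(seed)
            contigs = assemble(reads, TEMPLATE, m=1 << 24)
            assert len(contigs) == 1
            c = contigs[0].sequence
            assert c == covered or revcomp_str(c) == covered

    def test_repeat_resolved_by_spacing_but_not_by_2k_oracle(self):
        """An exact repeat with 2k <= R < 2k + delta - 1 is walked through by
        the spaced-seed assembler (the lagging k-mer pins the copy) while a
        plain 2k-mer de Bruijn walk breaks at it."""
        R = 60
        assert 2 * K <= R < 2 * K + DELTA - 1
        genome, covered, reads = _sim(11, repeats=[(2, R, 0.0)])
        contigs = assemble(reads, TEMPLATE, m=1 << 24)
        assert len(contigs) == 1
        c = contigs[0].sequence
        assert c == covered or revcomp_str(c) == covered
        oracle = kmer_oracle_assemble(reads, 2 * K)
        assert not any(covered in c or revcomp_str(covered) in c for c in oracle)

    def test_contig_windows_revalidate(self):
        """Every (2k+delta)-window of an emitted contig is in the filter."""
        from spacedseeds.assemble import build_graph as bg, _window_in

        genome, covered, reads = _sim(3, length=2000)
        filt, _ = bg(reads, TEMPLATE, m=1 << 24)
        contigs = assemble(reads, TEMPLATE, m=1 << 24)
        span = TEMPLATE.span
        for c in contigs:
            for i in range(0, len(c.sequence) - span + 1, 7):
                assert _window_in(filt, c.sequence[i : i + span], TEMPLATE)

    def test_two_scale_bridges_coverage_dip(self, rng):
        """When full-span windows are missing over a short stretch but their
        k-mers are present, the k-scale fallback walks across the dip."""
        from spacedseeds.assemble import extend_contig
        from spacedseeds.bloom import SeedBloom
        from spacedseeds.seqcodec import extract_seeds

        genome = random_dna(rng, 1200)
        gap_lo, gap_hi = 600, 620  # drop windows with origins in this range
        filt = SeedBloom(1 << 24, TEMPLATE)
        for S in extract_seeds(genome, TEMPLATE):
            if not (gap_lo <= S.origin < gap_hi):
                filt.insert(S)
        start = AuxSeedInfo(genome[: TEMPLATE.span], "blunt", "5p")
        plain = extend_contig(start, filt, TEMPLATE, two_scale=False)
        assert len(plain.sequence) < len(genome)
        bridged = extend_contig(start, filt, TEMPLATE, two_scale=True)
        assert bridged.sequence == genome
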