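# spacedseeds

Spaced-seed data structures for de Bruijn graph (DBG) assembly.

Long reads push DBG assemblers toward long k-mers, which inflate memory and
are rarely error-free.  A **spaced seed** sidesteps both problems: a pair of
`k`-mers `[k : k]` separated by a fixed gap of `Δ` bases.  Only the `2k` seed
bases are stored — `4k` bits regardless of `Δ` — while the seed's genomic
span `2k + Δ`, and with it its uniqueness in a genome, keeps growing.  Errors
that fall in the gap never touch the stored content at all.

This package implements, and makes testable on synthetic data:

* **2-bit codec** (`seqcodec`) — A/C/G/T ↦ 00/01/10/11 so complementation is
  bitwise NOT; seed extraction, canonical forms, FASTA/FASTQ ingest.
* **Strand-folded hashing** (`seedhash`) — four hash values per seed
  (left, right, odd, even strided substrings, each XOR-folded with its
  reverse complement) that swap pairwise under reverse complementation.
* **Bloom filter** (`bloom`) — the four values are the filter's `h = 4` hash
  functions, so membership is strand-canonical for free;
  `f = (1 − e^{−hn/m})^h` sizing math included.  At optimal load
  (`hn/m = ln 2`), `f = 6.25 %`, and 3×10⁹ seeds fit in ≈ 2 GiB.
* **Minifloat counter** (`minifloat`) — an 8-bit 1.4.3.-2 float (1 sign,
  4 exponent, 3 mantissa, bias −2) counting exactly to 16 and
  probabilistically (unbiased Morris increments) to 122,880.
* **Cascading counting filter** (`cascade`) — stage 1 records first
  observations; a byte array of minifloats engages from the second, with
  strand tracking in the sign bit and `−0` as the collision flag.
* **Hash-table record** (`seedtable`) — the deterministic layout:
  canonical content, two 15-bit saturating strand counters, 16 extension
  bits, 16 flag bits; spaced storage wins memory strictly for `Δ > 8`.
* **Error correction** (`correct`) — a single substitution leaves a
  two-of-four hit pattern that pins it to one half and one parity (~`k/2`
  candidate positions); unique re-validated fixes are applied.
* **Toy assembler** (`assemble`) — dual-wavefront contig extension where the
  lagging `k`-mer validates against already-assembled sequence, resolving
  exact repeats of length `R` with `2k ≤ R < 2k + Δ − 1` that break a plain
  `2k`-mer DBG; blunt/branch auxiliary tracking, garbage collection, short
  branch trimming, optional two-scale (`k` vs `2k + Δ`) walking.
* **Uniqueness profiler** (`profile`) and **simulator** (`simdata`).

## Worked example

```python
from spacedseeds import SeedBloom, SeedTemplate, extract_seeds
from spacedseeds.cascade import CascadeCounter
from spacedseeds.assemble import assemble
from spacedseeds.simdata import SimConfig, sim_genome, sim_reads

template = SeedTemplate(k=25, delta=30)          # span 80
cfg = SimConfig(genome_length=5000, read_length=150, coverage=30, seed=1)
genome = sim_genome(cfg)
reads = [seq for _, seq, _ in sim_reads(genome, cfg)]

contigs = assemble(reads, template, m=1 << 24)
print(f"{len(contigs)} contig(s), {len(contigs[0].sequence)} bp, "
      f"terminated by {contigs[0].terminated_by}")

counter = CascadeCounter(SeedBloom(1 << 24, template), seed=1)
for read in reads:
    for S in extract_seeds(read, template):
        counter.add(S)
est, both, coll = counter.count(extract_seeds(genome, template)[2500])
print(f"count ~{est:g}, both strands: {both}, collided: {coll}")
```

prints

```
1 contig(s), 4992 bp, terminated by blunt-end
count ~12, both strands: True, collided: False
```

The single 4992 bp contig is exactly the read-covered interval of the 5 kb
genome (uniform read starts leave the outer few bases unsequenced).  The
queried seed was covered by about 12 read windows across both strands —
counts up to 16 are exact, larger ones are unbiased estimates.

A command-line surface wraps the same functionality:

```sh
spacedseeds calc --h 4 --load optimal        # -> f = 6.25%
spacedseeds simulate genome --length 5000 --seed 1 --out genome.fa
spacedseeds simulate reads --genome genome.fa --coverage 30 --out reads.fq
spacedseeds assemble --reads reads.fq -k 25 --delta 30 --out contigs.fa
spacedseeds profile --genome genome.fa -k 8 -k 16
```

## Choosing k

The XOR fold that makes hashing strand-invariant is palindromic, so a
`k`-mer's hash input carries `4^⌊k/2⌋` distinct values.  Keep
`4^⌊k/2⌋` far above the number of stored seeds (and prefer odd `k`, which
also rules out the all-zero palindrome fold); see `docs/methods.md`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the package's own code paths: the Bloom
false positive rate at optimal load with four hash functions (as a
percentage), the maximum finite value of the 1.4.3.-2 minifloat counter from
a full 256-pattern enumeration, the largest integer range counted exactly by
that format, and the decoded value of the normalized pattern
(sign 0, exponent 0010, mantissa 001).  Results are written as JSON.
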