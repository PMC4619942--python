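# Methods

## The spaced seed

A spaced seed here is a pair of `k`-mers `[k : k]` separated by a fixed gap of
`Δ` bases.  A window of span `2k + Δ` contributes only its `2k` seed bases to
every data structure; the gap bases are read past and discarded.  Two
consequences drive the whole design:

* **Constant memory in Δ.** The stored content is `4k` bits regardless of the
  gap, so the genomic reach of a seed can grow without growing its footprint.
  Against storing the full window content (`2(2k + Δ)` bits), the spaced
  layout (`4k` content + a 16-bit doubled extension field) is strictly smaller
  for every `Δ > 8`, with an exact tie at `Δ = 8`.
* **Uniqueness grows with Δ.** A seed spanning `2k + Δ` bases carries the
  specificity of a much longer subsequence.  The `profile` module measures
  this directly: uniqueness is defined as the fraction of genomic seed
  *positions* whose canonical seed occurs exactly once genome-wide (strands
  collapsed, genome treated as linear).  This position-fraction definition is
  the assembly-relevant one and coincides with plain `2k`-mer uniqueness at
  `Δ = 0`.  Whether to count positions or distinct seeds was an open choice;
  we count positions.

Windows whose *seed* bases contain a non-ACGT character are skipped during
extraction; an `N` in the gap is irrelevant because the gap is never stored.
The encoder itself rejects non-ACGT input.

## Strand-folded hashing

Each seed yields four 64-bit hash values over strided substrings of the
concatenation `S` (1-based, `S(a:b:c)` = every `b`-th base from `a` to `c`):

    xL = H{fold(S(1:1:k))}        xO = H{fold(S(1:2:2k-1))}
    xR = H{fold(S(k+1:1:2k))}     xE = H{fold(S(2:2:2k))}

where `fold(x)` XORs the 2-bit packing of `x` with that of `revcomp(x)`
(substring taken before reverse complementation).  Under reverse
complementation the left/right pair and the odd/even pair swap, so a seed and
its reverse complement set and query the same four Bloom filter bits — the
filter is strand-canonical by construction, with no explicit canonicalisation
step.  `H` is a salted 64-bit FNV-1a accumulation with a splitmix64 avalanche
finalizer: fixed, documented, and identical across platforms, because
serialized filters embed its outputs.  The four values serve directly as the
filter's `h = 4` hash functions.

**Information loss of the fold (important limitation).** The folded string is
palindromic by construction (`fold[i] == fold[n-1-i]`), so a `k`-mer's folded
input takes only `4^⌊k/2⌋` distinct values (odd `k`: the middle code is
pinned).  Two consequences:

* every reverse-complement-palindromic string folds to all-zero bits (the
  documented degenerate input; odd `k` avoids it for the two `k`-mers, since
  no odd-length DNA string is its own reverse complement);
* when the number of stored seeds approaches `4^⌊k/2⌋`, distinct seeds start
  colliding on whole hash values and the measured false positive rate rises
  above the classical formula.  At `k = 8` the universe is only 65,536 halved
  to 256 per half — toy scales saturate it.  At the realistic end of the
  ladder (`k ≥ 16..32`) fold collisions are negligible and the measured FPR
  matches `(1 − e^{−hn/m})^h` within binomial sampling error (verified at
  loads 0.25, 0.5, ln 2 and 1.0 with `k = 31`).  Genome-scale tests in this
  package therefore run at `k = 25`; the `k = 8` end of the grid is used only
  for string-level censuses that do not touch the hashes.

The counting stage needs to *distinguish* strands, so it uses a second,
unfolded pair: `hF = H'{pack(S)}`, `hR = H'{pack(revcomp(S))}` under a
distinct salt, with `strand_hash_pair(revcomp(S)) == (hR, hF)`.

## Bloom filter and sizing

Standard Bloom arithmetic, exposed as functions: `fpr(h, n, m)`,
`optimal_h(m, n) = (m/n) ln 2`, and `size_for(n, h, f)` = smallest `m` with
`fpr ≤ f` (closed-form inversion then integer tightening).  At `h = 4` and
optimal load the FPR is exactly `2^-4 = 6.25 %`; holding `n = 3×10⁹` seeds at
that operating point takes `⌈4n/ln 2⌉` bits ≈ 2 GiB.  Positions are
`hash mod m` with no primality requirement — the avalanche finalizer makes
low-order bits usable.  `insert` returns the pre-insert hit pattern, which is
what the cascade and the corrector key off.  The bit array is a numpy `uint8`
buffer; serialization writes a fixed little-endian header (magic, version,
`k`, `Δ`, `m`, `h`, insert count) followed by the raw bytes.

A lone `k`-mer can be probed against the same bit array through its single
folded hash (`contains_kmer`) — this is the smaller of the two length scales
the assembler can walk at, with a correspondingly elevated false positive
rate (one hash value instead of four).

## Minifloat counting (1.4.3.-2)

One byte per counter: 1 sign bit (a strand flag, not an arithmetic sign),
4 exponent bits, 3 mantissa bits, bias −2:

    e = 0          c = t              (exact 0..7)
    1 ≤ e ≤ 14     c = (1 + t/8)·2^(e+2)
    e = 15         reserved, never produced (IEEE-inspired top-exponent
                   reservation); decodes as saturated

Every integer 0..16 is representable (17 is the first gap); the maximum
finite value is 122,880 at `e = 1110, t = 111`, giving five orders of
magnitude in one byte.  `−0` (sign set, magnitude zero) is excluded from
arithmetic and reserved as the collision flag.

Counters advance with a Morris-style probabilistic increment: from a state
whose distance to the next representable value is `g` (`g = 1` through 16,
`2^{e−1}` in band `e ≥ 2`), advance with probability `1/g`.  The expected
advance is exactly 1 per true event at every state, so decoded counts are
unbiased; counts ≤ 16 are exact because all gaps there are 1.  The format
itself does not dictate an increment rule; the Morris rule is the standard
unbiased choice, and replicated simulations (10,000 replicates per
logarithmic bin up to 10⁴) keep the mean within 5 % of truth.
Counters saturate at the maximum rather than wrapping.

## The cascade (two-stage counting)

Stage 1 is the membership filter; it records first observations.  When an
insert finds all four bits already set, the observation cascades to stage 2:
a byte array of `m2` minifloat counters (default `m2 = m/8` bytes, equal
memory to stage 1).  The strand-sensitive pair `(hF, hR)` mod `m2` gives the
coordinates `x` (forward) and `x'` (reverse); a seed and its reverse
complement address the same unordered pair with roles swapped.  The update
rules, with byte states classified as `+0`, `−0`, or nonzero:

| `x` | `x'` | action |
|---|---|---|
| 0 | 0 or −0 | `x` := count 2, sign 0 |
| nonzero | 0 or −0 | increment `x`, sign unchanged |
| 0 or −0 | nonzero | increment `x'`, sign := 1 |
| nonzero | nonzero | both := −0 (collision flag) |
| −0 | 0 | `x'` := count 2, sign := 1 |
| −0 | −0 | both stay −0 |

The `(−0, −0)` row is not printed upstream; it follows from treating `−0` as
nonzero for the collision case (to avoid secondary collisions) and is tested
explicitly.  Sign 1 ("seen on both strands") and `−0` are both sticky.  A
stage-1 all-hit caused by a false positive cascades like any other — the
structure cannot tell, and the first cascade then records a count of 2 for a
once-seen seed; this is the documented accuracy cost of the stage-1 FPR.
If `x == x'` (reverse-complement-palindromic seed or modulus coincidence)
the byte is treated as the forward coordinate; palindromic seeds otherwise
self-flag under the literal rules.

Queries read both coordinates: `−0` at either reports a collision; otherwise
the populated coordinate's decoded count is the estimate, falling back to 1
(stage-1 hit only) or 0.

## Deterministic hash table

`SeedRecord` is the deterministic alternative to the filter: canonical seed
content (`4k` bits), two 15-bit saturating strand counters (cap `2^15 − 1`,
never wrapping; we cap at `2^15 − 1` so the count fits its 15 bits), a
16-bit extension-presence
mask (4 bases × 2 directions × 2 seeds) and 16 bookkeeping flag bits.
Records are keyed by the canonical form rather than the first-observed
orientation — equivalent information with a simpler invariant.  Extensions
observed on the non-canonical strand are complemented and mirrored
(seed 1 ↔ seed 2, 5′ ↔ 3′) before being recorded, so the mask is frame
independent; `add_read` wires extensions from read context (the base before
the left seed, the two gap-boundary bases, the base after the right seed).

## Error correction

A single substitution in the seed bases knocks out exactly one of {L, R} and
one of {O, E}.  Pattern classes over the four-hash query:

* `(1,1,1,1)` — present; update the count if a counter is attached.
* exactly two hits forming {L|R} × {O|E} — single-correctable: candidate
  positions are the missed half ∩ missed parity (about `k/2` positions,
  always inside the stored seed, never the gap).  Each candidate × 3
  alternative bases is re-queried; a substitution survives if it restores
  the all-hit pattern and (when a counter is given) the corrected seed has a
  nonzero count.  The fix is applied only if **exactly one** survivor exists
  — precision over recall; ambiguity means insert-as-new.
* exactly one hit — possibly two substitutions; no cheap unique fix exists,
  so the default action is insert (a bounded two-substitution search was
  considered and rejected as default behaviour: quadratic cost, high
  ambiguity).
* everything else (0 or ≥3 hits, and the impossible L+R / O+E two-hit
  combinations) — absent: insert.

`correct_read` slides the rules across all windows left to right; a committed
substitution takes effect immediately so downstream windows see the corrected
sequence.  When FASTQ qualities are present, a fix is committed only if the
base being rewritten has quality below Q20 (default): high-confidence bases
are trusted.  Gap errors never require action by construction.

## Assembly (toy)

A node is a full `(2k + Δ)`-base window, held implicitly in the filter via
its seed.  Extending a contig rightward probes the four seeds of
`seq[-(span-1):] + b`: the probe's left `k`-mer lies `k + Δ` bases behind the
leading edge, so every step simultaneously advances the leading wave front
and asserts the lagging one against already-assembled sequence — this is
what walks through exact repeats of length `R` with `2k ≤ R < 2k + Δ − 1`
that break a plain `2k`-mer graph (verified against a string-level `2k`-mer
de Bruijn oracle).

Auxiliary data gives assembly its starting points: every read initially
contributes two blunt candidates (its end windows, with the gap bases taken
from the read — a seed alone does not determine them); the second read to
cross a junction with a different next base deposits a branch representative
(tracked in a canonical-frame extension registry during construction).
Garbage collection re-probes blunt candidates against the populated filter
and drops any that have since grown extensions; on tiled data exactly the
two terminal windows survive.

Numerical/termination choices:

* A false-positive extension needs only two non-genuine hash hits (the
  candidate shares `xL` and `xO` with the true window), so spurious
  candidates occur at roughly the *square root* of the four-hash FPR.  When
  several candidates hit, each must survive a depth-2 lookahead; a false
  branch survives each further step with geometrically decaying probability
  (`f` per node, per the false-branch argument: at `f = 6.25 %` a
  length-10 false branch survives a 3×10⁹-test Bonferroni correction with
  probability < 0.3 %).  The lookahead is the traversal-level form of
  trimming branches shorter than `2k − 1`; emitted contigs additionally pass
  `trim_branches` (drop contigs whose extension beyond the initiating
  window is < `2k − 1`, circular contigs exempt).
* Ambiguity that survives lookahead terminates the contig (`branch`) rather
  than forking the output; no candidate terminates it `blunt-end`;
  revisiting the start window closes it `circular`.
* Traversal order is deterministic (auxiliary entries sorted), contigs are
  deduplicated up to reverse complement and containment, so assemblies are
  reproducible byte for byte.
* Two-scale fallback (opt-in): when the full-span probe finds nothing, the
  trailing `(k−1)`-context is probed at scale `k` through the single folded
  hash; a unique candidate bridges short coverage dips.  Off by default
  because the single-value probe has elevated FPR.

## Synthetic worlds

The generator states the conditions the tests run under: i.i.d. uniform
genomes (default 5 kb) with repeat families planted non-overlapping
(count, length, divergence triples; divergence 0 plants exact duplicates),
reads of 150 bp at 30× coverage with uniform starts, random strand and
substitution-only errors (the corrector is substitution-based; indels are
out of scope), constant quality strings at the Phred score of the configured
error rate.  Count fixtures run 10,000 replicated increment streams per
logarithmic bin (powers of two up to 8192, plus 10⁴).  Everything derives
from one integer seed, byte-for-byte reproducibly.

What a green test does **not** establish: real error profiles (quality-
correlated, indel-bearing), real genome repeat structure, coverage biases,
or behaviour at `k` small enough for fold saturation (see above).  Uniform
read starts leave the outermost few bases of a linear genome uncovered, so
assembly exactness is asserted against the read-covered interval — bases
never sequenced cannot be assembled.

## Known limitations

* The fold's `4^⌊k/2⌋` information ceiling (above) makes small-`k`
  configurations unusable at scale; choose `k` with `4^⌊k/2⌋ ≫ n`.
* Reverse-complement-palindromic seeds self-collide in the cascade and are
  flagged as collisions.
* The assembler is a toy: in-memory auxiliary lists, no paired-end or
  variable-Δ mode, no scaffolding, no coverage-stratified assembly.
* The corrector fixes one substitution per window; two-error windows are
  inserted as new sequence.
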