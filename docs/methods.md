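# Methods

## The wave-identity model

A nucleotide sequence is summarised, per channel base `c ∈ {A,C,G,T}`, by
the gap series `d_1, d_2, …` where `d_i` counts the bases strictly between
the *i*-th and (*i*+1)-th occurrence of `c`. Under this convention `"AA"`
has gap 0, which makes the rule "zero gaps are dropped" meaningful while
keeping the 0-endpoint of the first bin usable when zero-dropping is
disabled. A sequence with fewer than two channel occurrences has an empty
identity. `N` never starts a gap but contributes to distances; input is
case-insensitive; coordinates are 0-based and half-open throughout.

Two invariances motivate the design:

* **Substitution blindness.** Changing any non-channel base to another
  non-channel base cannot move a channel occurrence, so for channel A the
  common C⇋T transition is completely invisible.
* **Indel softness.** Distances are binned in pairs (`0–2`, `3–4`, …,
  `37–38`, `39–9999`), so a ±1 change from a small indel either stays in
  the same bin or moves to an adjacent one. The matcher can treat
  adjacent-bin mismatches as free, making single small indels cost
  nothing.

The encoding is lossy by construction: within-bin variation, the entire
composition of non-channel stretches, and (with slicing) a fixed fraction
of the symbols are all discarded. Losing information is the point — both
reads and references pass through the same reduction, so comparisons
remain between like objects.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `channels` | `(A,)` | bases whose occurrence positions define gap series |
| `drop_zero_gaps` | true | discard gaps of 0 (adjacent channel bases) |
| `max_gap` | off | optional hard cutoff discarding gaps above a bound |
| `use_rle` | true | run-length compress repeated bin symbols |
| `slice_stride` | 1 | keep every *s*-th binned symbol |
| `packed` | true | 5-bit/symbol storage in the packed MGDB dialect |

A single channel is the default: one 5-bit-packed channel accounts for the
size ratios the encoding is meant to deliver (roughly 10% of the original
nucleotide count at stride 1 on random sequence, ~3.5% at stride 3), while
each extra channel adds a full second payload. Additional channels remain
available; when present, the matcher reports a reference only if *every*
channel produces a hit (intersection), which preserves the prefilter's
discard-only role.

Runs longer than 10 have no single RLE prefix, so they decompose greedily —
blocks of 10 first, then one remainder block, a remainder of 1 emitted
bare. Greedy decomposition is deterministic and decodes unambiguously.
Distances above 9999 clamp into the final catch-all bin rather than
erroring.

Slicing operates on the raw (pre-RLE) code with an explicit phase. A read
sliced at stride *s* aligns with a stride-*s* reference only when the
phases are compatible, so the query stage encodes each read at all *s*
phases (and both strands, since reads come from either) and takes the
union of hits. Databases are always written at phase 0.

## Matching

`find_matches` is seed-and-extend over the identity alphabet: all exact
`k`-symbol substrings of the decompressed reference identities are indexed
in a postings table (`k = 8` by default); each diagonal that shares at
least one exact seed with the read is scanned for *maximal* windows whose
mismatch count stays within the tolerance `t`. A mismatch costs 1, except
between bins of adjacent rank when `adjacent_free` is on (cost 0). Windows
shorter than `min_hit_len` (default 12 symbols) are discarded; overlapping
hits for the same (read, reference, strand) merge to the longest;
surviving hits sort by score (`length − 2·mismatches`) with `(ref_id,
ref_offset)` as the tie-break, capped at `max_hits_per_read`. Hit spans
convert back to approximate nucleotide lengths via bin-midpoint sums,
documented as estimates only.

`brute_force_matches` applies the identical window rules to *every*
diagonal with no seeding and is the correctness oracle. At `t = 0` with
strict costs every qualifying window is an exact run of at least
`min_hit_len ≥ k` symbols, so it necessarily contains a seed and the two
procedures agree exactly; the suite checks this on 200 randomized
instances. With `adjacent_free` on, a zero-cost window may contain
free adjacent-bin mismatches and hence no exact seed, so the guarantee is
deliberately stated for strict costs. For `t > 0` the indexed path's raw
(unmerged) windows are a subset of the oracle's; after overlap-merging the
two can select different cluster representatives, which is why the subset
law is asserted on unmerged windows.

`require_full_read` switches the matcher to containment mode: only hits
spanning the read's entire identity are reported. This is the natural
query for validation with error-free reads — the whole identity must occur
in the source — and gives a near-zero false-hit rate without tuning
`min_hit_len` against the read-length distribution.

### Permissiveness

The default parameters (`t = 2`, adjacent-free, `min_hit_len = 12`) are
prefilter settings: against a megabase-scale reference of random sequence
they will pass a large fraction of unrelated reads, because 12-symbol
near-matches arise by chance in identity space. That is intended — the
prefilter's contract is that true positives are never discarded, not that
false positives are rare. The suite therefore records how the false-hit
rate against an unrelated genome falls as `min_hit_len` grows (and
verifies it is below 5% by `min_hit_len = 20` with strict costs) rather
than asserting a fixed rate at the permissive defaults.

## Quality control and host subtraction

Reads are filtered before encoding: optional edge-`N` trimming, a minimum
length (default 50 nt), a minimum mean Phred score (default 20, FASTA
records skip the quality rule), and exact-string duplicate removal keeping
the first occurrence. Each dropped read is counted under the first rule
that rejected it. The QC thresholds are conventional defaults, exposed as
flags. Host subtraction encodes the reads once and removes any read with
at least one hit against the host database under the active match
parameters; survivors continue to the search.

## MGDB format

The packed dialect stores `MGDB` + version byte, a u16-LE-length-prefixed
profile block (`channels=A;bins=default;rle=1;slice=1;zero=drop;pack=1;
maxgap=none`), then per identity: id length (u8), id bytes, source length
(u32 LE), symbol count (u32 LE) and `ceil(5n/8)` payload bytes (canonical
symbol enumeration `'1'..'9','A'..'J','Z','a'..'i'` → 0..28, big-endian
bit order, zero-padded final byte). Multi-channel records emit one
sub-record per channel in profile order, so the channel is positional.
The text dialect is line-oriented and diff-able. Both round-trip
bit-exactly; truncation and bad magic are reported with byte offsets.

Compression statistics count the original size as nucleotide letters only
(headers and newlines excluded) and the compressed size as the packed
payload bytes only (record headers excluded); `shrink % = 100·(1 −
compressed/original)`, rounded to the nearest integer. Payload-only
accounting is documented with the stats because delimiter conventions
differ between tools.

## The simulator

`generate_genome` draws i.i.d. bases with a configurable GC content —
it emulates database references in size and composition but has none of
real genomes' repeat structure, skew or coding constraints, so
compression ratios and false-hit rates measured on it characterise the
*codec and matcher*, not any particular taxon. `mutate` applies per-base
substitutions split into transitions (A⇋G, C⇋T) and transversions —
`ts_fraction` defaults to 2/3 as a conventional simulator value
reflecting the observed excess of transitions — plus geometric-length
indels (mean 1.5). `simulate_reads` samples uniform start positions on
either strand (default 150 nt, within the short-read range), applies the
error model per read, draws Phred qualities from a normal
(mean 35, sd 3) truncated to [2, 41], and emits a truth table
(read id, source interval, strand, error counts). Parameter recovery —
empirical substitution rate and transition fraction within 3 binomial
standard errors at 10⁵ bases — is asserted in the suite.

## Problem sizes and numerical choices

The end-to-end suite runs at 1 Mb reference scale with 1,000 reads, and
property batteries at tens of kilobases; these sizes give stable
statistics (binomial standard errors well below the asserted margins)
while keeping the whole suite interactive. All random draws flow through
seeded `numpy` generators; every pipeline stage is a pure function of its
inputs and profile, and the suite asserts byte-identical reruns.
Degenerate inputs are defined, not errors: empty sequences, references
shorter than a seed, and empty databases all yield empty results.

## Known limitations

* Reads whose identity is shorter than `min_hit_len` symbols (A-poor
  reads, or very short reads) are invisible to the matcher by
  construction; at 150 nt and GC 0.5 this tail is negligible but it grows
  for extreme compositions.
* Identity-space coordinates map back to nucleotide positions only
  approximately (bin midpoints); the tool reports candidate subjects and
  coverage, not alignments.
* No gapped alignment in identity space, no e-value model, and no
  taxonomic resolution — downstream tools own those.
* Low-complexity real sequence (long homopolymers, tandem repeats)
  produces highly repetitive identities that inflate both RLE gains and
  spurious seed matches relative to the random-genome figures quoted here.
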