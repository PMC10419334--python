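# metawave

Lossy "wave identity" compression of nucleotide sequences, and a tolerant
matcher that uses those identities as a fast prefilter for subject
identification in metagenomic reads.

## The problem

Metagenomic classification compares millions of short reads against
reference databases measured in gigabytes. Most of that work is wasted on
references the read obviously does not come from. `metawave` attacks the
problem with a deliberately lossy sequence encoding: instead of the full
`ACGT` text, each sequence is reduced to the series of distances between
consecutive occurrences of a single *channel* base (A by default) — the
"wavelength" of that base along the strand. Two sequences from the same
organism keep nearly the same wave even under substitutions (any change
among the non-channel bases is invisible) and small indels (a distance
moves to a neighbouring bin at worst). Matching in this small identity
space quickly discards obvious non-matches, leaving a short candidate list
for an exact aligner.

## The encoding

For channel A and a sequence `s`:

1. **Gap extraction** — record `d_i`, the number of bases strictly between
   the *i*-th and (*i*+1)-th `A`; zero distances are dropped by default.
2. **Binning** — each `d_i` maps to one symbol by range:
   `0–2→'1'`, `3–4→'2'`, …, `37–38→'J'`, `39–9999→'Z'` (20 bins; larger
   distances clamp to `'Z'`). Within-bin variation is deliberately erased.
3. **Run-length encoding** — a run of 2–10 identical symbols becomes a
   lowercase prefix plus the symbol (`'AAAA'` → `'gA'`); longer runs split
   greedily into blocks of 10.
4. Optionally, **slicing** keeps every *s*-th symbol for further shrinkage,
   and the 29-symbol alphabet packs at 5 bits/symbol on disk (the MGDB
   format, with a text dialect for debugging).

Matching is seed-and-extend over the identity alphabet: exact *k*-symbol
seeds (default `k = 8`) are looked up in a postings index, and each seeded
diagonal is scanned for maximal windows with at most *t* costed mismatches
(default `t = 2`; mismatches between adjacent bins can be made free to
absorb indels). A brute-force sliding-window oracle validates the indexed
path in the test suite.

## Worked example

Simulate two unrelated 200 kb genomes, compress them, and identify the
source of 500 error-free reads drawn from the first:

```
metawave simulate genome --length 200000 --seed 7 --id n_meningitidis_sim --out ref.fa
metawave simulate genome --length 200000 --seed 8 --id k_quasipneumoniae_sim --out ref2.fa
cat ref.fa ref2.fa > refs.fa
metawave compress --in refs.fa --out refs.mgdb
metawave simulate reads --genome ref.fa --n 500 --seed 9 --out-fastq reads.fq --out-truth truth.tsv
metawave query --db refs.mgdb --reads reads.fq --no-dedup --out hits.tsv
metawave report --hits hits.tsv --db refs.mgdb --out coverage.tsv
```

which prints

```
original_bytes	400000
compressed_bytes	41962
shrink_pct	90

reads_in	500
reads_kept	500
host_removed	0
reads_matched	500
matched_pct	100.0
```

and writes the coverage table

```
ref_id	covered	total	coverage_pct	n_hits	n_reads
n_meningitidis_sim	32808	37441	87.6	16417	500
k_quasipneumoniae_sim	30380	37235	81.6	15718	498
```

Reading the numbers: the two genomes (400,000 nt) compress to 41,962 bytes
of packed identity payload, a 90% reduction. Every read is matched
(`matched_pct 100.0`) and the true source ranks first by identity-space
coverage. The second row illustrates the method's character: at the
default permissive settings the prefilter also reports hits against an
unrelated genome — it is designed to *discard certain non-matches*, not to
adjudicate between similar candidates, which is the downstream aligner's
job. Tightening `--min-hit`/`--tolerance` (or `--strict-adjacent`) trades
that permissiveness for specificity; the test suite records the curve.

A `--host-db` option removes reads matching a host reference before the
search, and `metawave query` applies mean-quality, length and duplicate
filters (`--min-qual`, `--min-len`, `--no-dedup`) first.

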