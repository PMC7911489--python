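# Methods

## Model and assumptions

The pipeline treats every small RNA read as one of four molecule states
relative to an annotated mature miRNA: unaltered, 3′-trimmed, 3′-tailed, or
both. Two structural assumptions are built in:

* **5′ ends are fixed.** A read must reproduce its reference's 5′ prefix
  exactly; 5′ isomiRs, internal substitutions and indels are not modeled.
  This matches the biology being measured — plant miRNA turnover acts on
  the 3′ end via exonucleolytic trimming and nucleotidyl-transferase
  tailing — and keeps the decomposition identifiable.
* **Modifications are bounded at 7 positions each.** Trimming depth `t` and
  tail length `u` are capped independently at 7 (`--max-trim`, `--max-tail`).
  The bounds are independent, not joint (`t + u` may reach 14): each process
  is evaluated "up to the seventh position" in its own right.

Classification is canonical: the matched prefix is maximal, so a tail never
begins with the base that would extend the reference match — a tail base
that coincidentally continues the reference is absorbed into the match.
Consequently the reported (t, u) is the minimal-modification explanation per
reference, and the reference with minimal `t + u` overall is assigned. An
exact tie between distinct references is reported as `ambiguous` and kept
out of the indexes; this prevents one molecule from being counted for two
miRNAs. Reads matching no reference within the bounds are `unclassified`.
Both categories are carried through to the outputs and the conservation
check, never silently dropped.

### Masked-genome filter

The filter is an exact-match search (zero mismatches, both strands) of each
unique read against the genome with mature miRNA footprints replaced by `N`.
Exact matching is the strictest reading of "mapping": it is deterministic,
self-contained, and identical in effect to an aligner for perfect genomic
reads. Reads that map with mismatches to the genome (sequencing errors,
SNPs) are *retained* here where a tolerant aligner would drop them; such
reads then land in `unclassified` unless they happen to decompose against a
reference, so the practical difference is confined to near-matching genomic
background. A reference whose exact sequence (either strand) survives in
the masked genome is excluded before analysis, because its reads are
systematically absorbed by the filter; exclusions are written to
`excluded_crossmapping.tsv` with one match coordinate each.

### Indexes and statistics

Per miRNA and replicate, `trimming_index = #(t ≥ 1)/total` and
`tailing_index = #(u ≥ 1)/total` over classified reads only — each read
counts once, irrespective of degree, and a trimmed-and-tailed read counts in
both numerators. A miRNA with zero classified reads in a replicate has *no*
index there (0/0 is not evidence of zero modification); per-line means are
taken over the replicates where the index is defined, and the number used is
recorded (`n_used`). Index differences subtract the reference line's mean
from the line's mean per miRNA.

Lines are compared with a two-sided paired t-test on per-miRNA mean-index
pairs (scipy's `ttest_rel`), requiring at least `--min-pairs` (default 3)
shared miRNAs. Degenerate inputs are flagged rather than guessed at:
zero-variance differences with zero mean give no p-value; zero variance with
nonzero mean is reported at the smallest positive float with a note.
p-values are Benjamini–Hochberg corrected within each modification across
*all* tests of the invocation — one run is one comparison set, regardless of
how lines group into studies. Boxplot exports annotate lines with
`*`/`**`/`***` at q < 0.05/0.01/0.001.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_trim`, `max_tail` | 7, 7 | per-process position bounds (nt) |
| `min_len`, `max_len` | 18, 32 | read length gate at intake (nt) |
| `min_pairs` | 3 | minimum paired miRNAs to emit a p-value |
| `min_total` | 1 | minimum classified reads per miRNA × replicate |

The 18–32 nt intake gate suits real libraries dominated by 20–24 nt small
RNAs. Note its interaction with trimming: a 20-nt mature trimmed by 3 is a
17-nt read. Analyses that must count deep trims — including every simulation
in this repository — should set `min_len` to (shortest mature − `max_trim`),
i.e. 13 for the simulated 20–22 nt matures; otherwise deep-trim isomiRs are
length-filtered and the trimming index is biased downward.

## The synthetic-data generator

`trimtail.simulate` emulates exactly the statistical structure the analysis
assumes: per line, each read of miRNA *i* is independently trimmed with
probability π_t (depth ~ geometric, success 0.5, truncated at 7) and tailed
with probability π_u (length likewise; bases drawn U-rich — P(T) = 0.8,
0.0667 each otherwise — reflecting HESO1/URT1 uridylation), plus genomic
background reads (20–24 nt exact substrings of unmasked genome) that the
filter must remove. Defaults: 20 MIR loci (one guide + one star each,
20–22 nt, random strand) in a 50 kb genome, 3 replicates, expected 2,000
reads per mature with log-normal abundance weights (mean 1, σ = 1),
1,000 background reads, π_t = π_u = 0.10 (wild-type-scale modification).
Expected depth applies to every mature reference; star-specific depletion
can be emulated via the abundance machinery but is not imposed by default.

Design choices that make the simulation a *calibration-grade* fixture:

* **Engineered identifiability.** Rejection sampling guarantees that every
  mature's first `L − 7` bases are unique among matures and absent (both
  strands) from the masked genome. This makes two guarantees exact rather
  than merely probable: every planted miRNA read with t, u ≤ 7 survives the
  genome filter, and no simulated read is ambiguous between references.
  Without the prefix condition, a 13-nt trimmed read collides with a 50 kb
  genome at ~0.7% per read — enough to corrupt recovery tests.
* **Collision-free tails (default on).** When a read is both trimmed and
  tailed, the first tail base is redrawn to differ from the reference base
  it replaces, so classification recovers the generated (t, u) exactly and
  index estimates are unbiased. With `collision_free=False`, a fraction of
  tails re-extends the match and indexes *underestimate* the true rates —
  a documented bias, available for robustness studies.
* **Determinism.** All randomness flows from `(seed, line_id, replicate_id)`
  via hashed seed sequences; the same seed yields byte-identical FASTA,
  GFF3 and FASTQ. Abundance weights depend only on (seed, line), so
  replicates of a line share expected depths and counts are Poisson around
  them. Optional beta-distributed per-replicate jitter on π
  (`replicate_jitter`, off by default) supports type-I/power studies under
  overdispersion.

What the generator does **not** emulate: sequencing errors, adapter
remnants, ligation bias, 5′ isomiRs, expression differences between lines,
or correlated study effects. Passing recovery and error-rate tests on this
generator therefore demonstrates the pipeline's correctness under its own
model assumptions — not robustness to artifacts the analysis has no
components to address.

## Validation results and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) recompute:

* classifier vs. brute-force enumeration over all (ref, t ≤ 7, u ≤ 7)
  decompositions: 1,000 random reads × 20 Hamming-separated references;
* parameter recovery at the generator's reference conditions (20 loci,
  3 replicates, ~2,000 reads per mature, π_t = 0.30, π_u = 0.10): per-index
  z-scores against binomial standard errors at realized depths, and mean
  absolute error;
* paired-t type-I error over 200 simulated null line pairs (8 loci,
  ~150 reads per mature — the t-statistic's calibration does not depend on
  depth, so the null study uses a lean configuration) at α = 0.05;
* detection rate over 50 simulations of a +0.15 trimming shift (~300 reads
  per mature), counting a success when trimming p < 0.01 *and* the median
  trimming ID exceeds +0.10;
* the hand-checkable statistics oracles (BH step-up example; the 3-pair
  paired t against the df = 2 closed form `P(T ≤ t) = 1/2 + t/(2√(t²+2))`).

The "every index within 3 binomial SEs" recovery check is itself a
statistical property: with 80 indexes an exactly unbiased estimator exceeds
3 SE somewhere in roughly one seed in five (binomial tail ≈ 0.27% per
index). The reported `frac_within_3se` and `max_abs_z` should be read
accordingly.

## Numerical and degenerate-input policies

* All sequences are canonicalized to uppercase DNA (U→T) at load time;
  reads containing other characters are dropped at intake (counted and
  logged) and rejected with an error at classification.
* Coordinates are 1-based inclusive at every file boundary and in all
  reports, 0-based half-open internally; coverage windows accept both
  conventions explicitly (`Window.from_gff` / `Window.from_bed`).
* Zero-variance paired differences are detected with a relative tolerance
  (10⁻⁹ of the dominant scale) so that constant differences assembled from
  floats are treated as degenerate rather than fed to the t-test.
* Empty libraries are an error for coverage (RPM needs a positive total)
  but legal everywhere else; an empty locus list masks nothing; masking is
  idempotent and overlapping loci mask their union.
* Annotation-vs-supplied mature sequence conflicts are reported (logged per
  record), never resolved silently; the annotation-derived sequence is used.
* A collapsed reference whose members carry conflicting guide/star labels is
  a hard error.

## Known limitations

* The exact-match filter differs from a mismatch-tolerant aligner for
  near-matching genomic reads (see above); with real, error-containing data
  the `unclassified` bin absorbs the difference.
* Multi-offset placement in coverage profiles counts a read at every window
  offset where it matches; repetitive windows therefore over-represent
  repeated reads.
* Substring search is linear per (read, chromosome); for genomes of
  hundreds of megabases an indexed search would be preferable. The intended
  scale — one plant genome, tens of libraries — runs in minutes.
* The paired t-test assumes per-miRNA index differences are approximately
  normal and exchangeable; very low-depth miRNAs violate normality, and
  `--min-total` exists to gate them out.
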