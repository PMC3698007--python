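# Methods

## Scope and model

`wgspipe` covers the stages of a multi-subject WGS SNP pipeline that run on
a single machine: manifest-driven pre-processing of raw reads, and
aggregation of per-subject SOAPsnp output into multi-sample genotype
matrices. Alignment and SNP calling themselves are external; the merge
stage consumes whatever coordinate-sorted SOAPsnp files an external caller
(or the fixtures module) places under the directory contract
`<workdir>/<subject>/snp/<chrom>.txt[.gz]`.

## Master manifest and naming

One text line per subject: unique id, raw-read locator(s) (a single
`.bam`/`.sam`, or two `;`-separated FASTQ locators, mate 1 first), and an
output prefix. Lines starting with `#` and blank lines are skipped, and
runs of spaces/tabs separate fields — standard manifest conventions.
Locators are opaque strings; only the local-filesystem backend resolves
them here, keeping object-store URLs valid as names but out of scope.
Record order is authoritative: it fixes the column order of every genotype
matrix. Artifact names follow
`<subject_id>.<stage>[_<mate>][.<chunk zero-padded to 4>].<extension>`,
which is injective over (subject, stage, mate, chunk) so parallel runs of
many subjects can share one output namespace. The 4-digit zero-padded chunk
index and dot-separated stage tokens are this package's own convention; any
deterministic, collision-free scheme driven by the unique id would do.

## Alignment extraction

BAM stores a reverse-strand alignment reverse-complemented, so extraction
undoes that (reverse-complement the sequence, reverse the quality string)
to recover reads in sequencing orientation. Secondary (0x100) and
supplementary (0x800) records are copies and never emitted; unmapped
primaries *are* extracted because they carry raw reads that re-alignment
needs; duplicate-flagged reads are kept by default (`drop_duplicates=True`
to discard), since the aim is recovering the full raw read set. Mates are
paired by template name with flags 0x40/0x80 assigning the slot; the
name-keyed buffer holds only currently-unpaired templates, so memory is
proportional to how far mates stray apart, not to file size (for
name-adjacent BAM this is O(1); for coordinate-sorted BAM it is bounded by
the insert-size spread). Templates whose mate never appears are handled by
policy: `error`, `separate_file`, or `drop` (default; the count is always
reported).

## Paired-FASTQ splitting

Splitting reads both mates' streams in lockstep, verifying at every ordinal
that the template names agree (after stripping `/1`, `/2`) and that both
streams end together. Records are moved as raw 4-line blocks, so the
concatenation of a mate's chunks is byte-identical to its input — the
property the round-trip tests assert. Default chunk size is 4,000,000
read pairs per chunk: at 100 bp reads this keeps a gzipped chunk comfortably
under common single-object transfer limits while leaving enough chunks for
parallel loading. Chunks are gzip-compressed by default. The chunk manifest
is one line per chunk pair — `locator TAB md5 TAB locator TAB md5` — with
literal `0` placeholders when checksums are skipped.

## The quality-SNP filter

SOAPsnp reports a Phred-scaled genotype quality `Q = −10·log₁₀(P_error)`.
For confidence level `c` the cutoff is `⌊−10·log₁₀(1−c)⌋` and a record
passes only with `Q` strictly greater, so every accepted call satisfies
`1 − 10^(−Q/10) ≥ c`. With the default `c = 0.95` the cutoff is 13 and the
smallest passing quality, 14, corresponds to 96.0% confidence. The log is
base 10 (the Phred convention), and a small epsilon (1e-9) is added before
flooring so exact cutoffs like 10 and 20 survive floating-point
representation of `1−c`.

Read support: the best and second-best bases must each be corroborated by
at least `min_unique_reads` (default 2) *uniquely aligned* reads. Unique
counts are used for both bases — the alternative reading, total aligned
reads for the second base, is looser and less robust to multi-mapping
artifacts. By default the second-base rule applies to every record
(`both_bases`); `het_only` restricts it to heterozygous calls, because a
clean homozygous site has no genuine second allele and the literal rule can
discard it (real datasets retain millions of homozygous SNPs, which
suggests callers in practice behave like `het_only`; both modes are
first-class and tested).

## Genotype decoding and classes

The consensus is one IUPAC code: A/C/G/T decode to homozygous pairs, the
six two-way codes (R,Y,S,W,K,M) to heterozygous pairs, and N plus the
three/four-way codes are undecodable — such records are dropped from
matrices and summaries with a logged count. Against the reference base a
decoded pair is reference (not a SNP, not counted), homozygous-alternate,
heterozygous (one reference allele), or het2 (two distinct non-reference
alleles, the rare class). The four classes partition all 10 unordered
genotypes × 4 references (verified exhaustively in the tests), and the
summary total is the sum of the three SNP classes by construction.

## Streaming merge

The k-way merge keeps a heap of (position, stream index) with exactly one
head record per stream — memory independent of file length, verified by an
instrumented test. All records at the minimum position form one row; ties
across subjects are resolved by manifest order, which also fixes column
order. Reference-base disagreement at a shared position aborts the merge
(it indicates subjects called against different reference builds, e.g.
hg18 vs hg19). Sortedness is enforced while streaming; duplicate positions
within one subject are an error by default (`keep_first` optional). A cell
is the sorted two-allele string; the missing code (default `NN`) is
deliberately ambiguous between homozygous-reference, no-coverage, and
filtered-out — the inputs do not distinguish them — and is configurable.
The matrix includes the reference-base column; a transposed
association-tool export (`write_plink_transposed`, `0 0` for missing) is
provided separately.

## Metrics and retry

Transfer-like steps run under a retry wrapper: up to 3 attempts, fixed
300 s wait between them (within the practical 5–10 min advice for cloud
transfer failures), with the sleeper injected so tests run instantly. Every
attempt appends one tab-separated line (ISO-8601 timestamps, 1-based
gapless attempt numbers, status success/retried/failed) to an append-only
log; the format round-trips losslessly.

## Synthetic data

The generators produce what the real pipeline consumes, scaled down and
with exact bookkeeping: SOAPsnp files with an exact class composition
(largest-remainder apportionment; a nonzero fraction that would round to
zero is rejected), a controlled passing fraction where each failing record
violates exactly one criterion at its boundary (quality 13; a unique count
of 1) so the strict-inequality and at-least-two rules are exercised
independently; passing qualities are uniform on 14..60. Reference bases are
a pure function of the coordinate so independently generated subjects never
disagree at shared sites. FASTQ pairs have matched template names and
uniform-random sequence; SAM fixtures carry the exact expected extraction
output, including reverse-flag restoration. Everything is a pure function
of (spec, seed). What these fixtures do *not* emulate: realistic base-error
and quality profiles, coverage variation, linkage structure, allele
frequencies, or a real reference genome — passing tests establish the
plumbing and the filter/merge semantics, not calling accuracy on real data.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen as the
smallest that still exercise each contract: merges up to 10 subjects ×
10,000 records against a load-everything brute-force oracle, 100 random
class-composition specs, splits up to 100,000 read pairs, and SAM fixtures
with a few hundred templates. Published full-scale figures that depend on
the original 44-subject dataset (per-subject SNP counts, the ~15M-unique-SNP
union, wall-clock and cost numbers) are not reproducible from synthetic
data; of them only the internal class-count identity (total = homozygous +
heterozygous + het2) is checked, using the published per-subject counts as
inputs.

## Known limitations

* No cloud/object-store backends, cluster orchestration, or remote
  monitoring; locators beyond the local filesystem are accepted as names
  only.
* The merge assumes one chromosome per input file and per-subject sortedness
  (violations are detected, not repaired).
* `het_only` vs `both_bases` changes which records survive; the default is
  the stricter literal rule, so counts on real data may run low compared to
  pipelines that exempt homozygous calls.
* Extraction buffers unpaired templates by name; a BAM whose mates are
  arbitrarily far apart (or missing wholesale) grows that buffer
  accordingly.
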