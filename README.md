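# wgspipe

Manifest-driven pre-processing and multi-subject SNP aggregation for
whole-genome sequencing (WGS) projects.

## The problem

A WGS project with tens of subjects produces raw reads as BAM or paired
FASTQ files of hundreds of gigabytes each. Before alignment the reads must
be recovered from BAM (undoing reverse-strand storage) and the paired FASTQ
must be split into mate-synchronized chunks so downstream aligners can load
them in parallel. After per-subject SNP calling, each subject's variants
arrive as per-chromosome, coordinate-sorted SOAPsnp-format text files —
a non-standard format that association tools cannot consume directly.
`wgspipe` implements these locally-computable stages for people running
multi-sample WGS pipelines: bioinformaticians who need the glue between
sequencing deliverables, a cluster aligner/caller, and GWAS tooling.

## The method

A single plain-text **master manifest** (one line per subject:
`<id> <read locator(s)> <output prefix>`) drives every stage and a
deterministic naming convention (`<id>.<stage>[_<mate>][.<chunk>].<ext>`)
that makes all artifact names collision-free.

The core algorithm is a **streaming k-way merge-sort** over the subjects'
coordinate-sorted SNP streams, one chromosome at a time. It holds exactly
one head record per stream (memory ∝ number of subjects, independent of
file size) and emits one row per variant position. A subject's genotype
enters a row only if its record is a *quality SNP*:

* Phred-scaled genotype quality `Q = −10·log₁₀(P_error)` strictly greater
  than `⌊−10·log₁₀(1−c)⌋` for confidence `c` (default `c = 0.95`, cutoff 13,
  so every accepted call has ≥ 95% confidence);
* at least 2 uniquely aligned reads corroborating both the best and the
  second-best base (optionally only for heterozygous calls).

The consensus IUPAC code is decoded to an allele pair (`R`→`AG`, `C`→`CC`,
…), written as a two-character cell in a chromosome-based genotype matrix
(one row per marker, one column per subject, `NN` for missing), and
classified as homozygous-alternate, heterozygous, or het2 (two distinct
non-reference alleles) for the per-subject summary table.

## Worked example

```bash
# a two-subject project: synthesize per-subject SNP files
wgspipe fixtures soapsnp --seed 1 --n-records 100 --out work/S1/snp/chr1.txt
wgspipe fixtures soapsnp --seed 2 --n-records 100 --out work/S2/snp/chr1.txt
printf 'S1\t/data/s1.bam\t/out\nS2\t/data/s2.bam\t/out\n' > manifest.txt

wgspipe merge manifest.txt --snp-dir work --chroms chr1 --out genotypes
```

which prints:

```
wrote 1 genotype file(s)
S1	homo=50	het=45	het2=5	total=100
S2	homo=50	het=45	het2=5	total=100
```

Every record in these fixtures passes the default filter, so each subject's
100 records split into the generator's 50/45/5 homozygous/heterozygous/het2
class mix, and `total` is always the sum of the three classes.
`genotypes/chr1.genotype.txt` then holds the merged matrix:

```
#chrom	pos	ref	S1	S2
chr1	100	A	AC	CC
chr1	200	A	CC	AT
chr1	300	A	AT	AC
```

— at position 100 subject S1 carries a heterozygous `AC` call and S2 a
homozygous `CC`. A row appears at every position where at least one
subject has a passing call; a subject without one there gets the missing
code `NN`.

`wgspipe preprocess manifest.txt --subject <id>` runs the other stage:
BAM→FASTQ extraction (if needed), synchronized splitting, and a chunk
manifest with MD5 checksums; `--metrics FILE` appends one TSV line per
step/attempt, and transfers retry after a configurable wait.

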