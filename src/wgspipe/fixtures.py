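"""Seeded synthetic-data generators for every pipeline stage.

Real WGS inputs are hundreds of gigabytes; these generators produce small,
fully deterministic stand-ins with known ground truth so each stage can be
tested end to end without any external data:

* :func:`generate_soapsnp_file` — a coordinate-sorted SOAPsnp file with a
  controlled mix of genotype classes and an exact pass/fail bookkeeping
  (failing records violate exactly one quality criterion at its boundary);
* :func:`generate_fastq_pair` — a valid mate-synchronized FASTQ pair;
* :func:`generate_sam` — a minimal SAM file plus the exact FASTQ expected
  from extraction, including reverse-complement handling and records that
  extraction must ignore.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .errors import FixtureSpecError
from .merge import ClassCounts
from .preprocess import reverse_complement
from .soapsnp import (
    DEFAULT_N_COLUMNS,
    GenotypeClass,
    SnpRecord,
    serialize_snp_record,
)

_BASES = "ACGT"

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

#: Failure modes a non-passing record can be generated with; each violates
#: exactly one default filter criterion at its boundary.
FAIL_MODES = ("quality_boundary", "best_unique_low", "second_unique_low")


@dataclass(frozen=True)
class SoapsnpFixtureSpec:
    """Recipe for one synthetic per-chromosome SOAPsnp file."""

    chrom: str = "chr1"
    n_records: int = 100
    class_mix: tuple[float, float, float] = (0.5, 0.45, 0.05)  # homo, het, het2
    pass_fraction: float = 1.0
    position_step: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise FixtureSpecError("n_records must be >= 0")
        if self.position_step < 1:
            raise FixtureSpecError("position_step must be >= 1")
        if any(f < 0 or f > 1 for f in self.class_mix) or not (
            abs(sum(self.class_mix) - 1.0) <= 1e-9
        ):
            raise FixtureSpecError("class_mix must be fractions summing to 1")
        if not (0.0 <= self.pass_fraction <= 1.0):
            raise FixtureSpecError("pass_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class RecordTruth:
    pos: int
    genotype_class: GenotypeClass
    passes: bool
    fail_mode: str | None = None


@dataclass(frozen=True)
class FixtureTruth:
    """Ground-truth bookkeeping for a generated SOAPsnp file."""

    records: tuple[RecordTruth, ...]
    expected_counts: ClassCounts = field(init=False)

    def __post_init__(self) -> None:
        homo = het = het2 = 0
        for r in self.records:
            if not r.passes:
                continue
            if r.genotype_class is GenotypeClass.HOMOZYGOUS:
                homo += 1
            elif r.genotype_class is GenotypeClass.HETEROZYGOUS:
                het += 1
            elif r.genotype_class is GenotypeClass.HET2:
                het2 += 1
        object.__setattr__(
            self,
            "expected_counts",
            ClassCounts(homozygous=homo, heterozygous=het, het2=het2),
        )


def _exact_counts(n: int, fractions: Sequence[float], what: str) -> list[int]:
    """Largest-remainder apportionment of n items over the fractions.

    Raises when a nonzero fraction would be rounded away entirely, because
    then the generated file could not realize the requested composition.
    """
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    for f, c in zip(fractions, counts):
        if f > 0 and c == 0 and n > 0:
            raise FixtureSpecError(
                f"cannot realize {what}: fraction {f} of {n} records rounds to 0"
            )
    return counts

_HET_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def _consensus_for_class(
    rng: random.Random, cls: GenotypeClass, ref: str
) -> tuple[str, str, str]:
    """Return (consensus code, best base, second base) realizing the class."""
    alts = [b for b in _BASES if b != ref]
    if cls is GenotypeClass.HOMOZYGOUS:
        alt = rng.choice(alts)
        return alt, alt, ref
    if cls is GenotypeClass.HETEROZYGOUS:
        alt = rng.choice(alts)
        return _HET_CODE[frozenset((ref, alt))], alt, ref
    a, b = rng.sample(alts, 2)
    return _HET_CODE[frozenset((a, b))], a, b


def generate_soapsnp_file(
    spec: SoapsnpFixtureSpec,
) -> tuple[str, FixtureTruth]:
    """Generate one sorted SOAPsnp file's text and its ground truth.

    Positions are ``i * position_step`` (1-based, strictly increasing).
    Passing records draw quality uniformly from 14..60 with unique read
    counts >= 2 for both bases; each failing record sits exactly on one
    criterion boundary (quality 13, or a unique count of 1) while
    satisfying the other criteria, so every rule is exercised in isolation.
    """
    rng = random.Random(spec.seed)
    n = spec.n_records
    class_counts = _exact_counts(n, spec.class_mix, "class_mix")
    n_pass = round(spec.pass_fraction * n)

    classes: list[GenotypeClass] = (
        [GenotypeClass.HOMOZYGOUS] * class_counts[0]
        + [GenotypeClass.HETEROZYGOUS] * class_counts[1]
        + [GenotypeClass.HET2] * class_counts[2]
    )
    rng.shuffle(classes)
    pass_flags = [True] * n_pass + [False] * (n - n_pass)
    rng.shuffle(pass_flags)

    lines: list[str] = []
    truths: list[RecordTruth] = []
    for i, (cls, passes) in enumerate(zip(classes, pass_flags)):
        pos = (i + 1) * spec.position_step
        # ref depends only on the coordinate so independently generated
        # samples always agree on the reference at shared sites
        ref = _BASES[pos % 4]
        consensus, best, second = _consensus_for_class(rng, cls, ref)
        fail_mode = None
        quality = rng.randint(14, 60)
        best_unique = rng.randint(2, 40)
        second_unique = rng.randint(2, 40)
        if not passes:
            fail_mode = rng.choice(FAIL_MODES)
            if fail_mode == "quality_boundary":
                quality = 13
            elif fail_mode == "best_unique_low":
                best_unique = 1
            else:
                second_unique = 1
        depth = best_unique + second_unique + rng.randint(0, 10)
        record = SnpRecord(
            chrom=spec.chrom,
            pos=pos,
            ref_base=ref,
            consensus=consensus,
            quality=quality,
            best_base=best,
            best_unique_count=best_unique,
            best_all_count=best_unique + rng.randint(0, 5),
            second_base=second,
            second_unique_count=second_unique,
            second_all_count=second_unique + rng.randint(0, 5),
            depth=depth,
        )
        lines.append(serialize_snp_record(record))
        truths.append(
            RecordTruth(
                pos=pos, genotype_class=cls, passes=passes, fail_mode=fail_mode
            )
        )
    text = "\n".join(lines) + ("\n" if lines else "")
    return text, FixtureTruth(records=tuple(truths))


def generate_fastq_pair(
    n_pairs: int, read_len: int = 100, seed: int = 0
) -> tuple[str, str]:
    """Generate a mate-synchronized FASTQ pair as two text blobs."""
    if n_pairs < 0:
        raise FixtureSpecError("n_pairs must be >= 0")
    if read_len < 1:
        raise FixtureSpecError("read_len must be >= 1")
    rng = random.Random(seed)
    quals = "".join(chr(q) for q in range(33 + 2, 33 + 41))
    out1: list[str] = []
    out2: list[str] = []
    for i in range(n_pairs):
        name = f"tpl_{seed}_{i:07d}"
        for mate, out in ((1, out1), (2, out2)):
            seq = "".join(rng.choices(_BASES, k=read_len))
            qual = "".join(rng.choices(quals, k=read_len))
            out.append(f"@{name}/{mate}\n{seq}\n+\n{qual}\n")
    return "".join(out1), "".join(out2)


@dataclass(frozen=True)
class SamTemplate:
    """One sequencing template for SAM generation.

    ``seq1``/``seq2`` are the sequences *as stored* in the SAM record (a
    reverse-flagged mate is stored reverse-complemented); ``None`` for a
    mate means the template is a singleton.  Extra flag bits (0x10, 0x100,
    0x400, 0x800, 0x4) are honored; 0x1 and the mate-slot bits are added
    automatically.
    """

    name: str
    seq1: str | None
    seq2: str | None
    flags1: int = 0
    flags2: int = 0


def generate_sam(
    templates: Sequence[SamTemplate], seed: int = 0
) -> tuple[str, str, str]:
    """Emit a minimal valid SAM plus the exact extraction-expected FASTQ.

    Returns ``(sam_text, expected_mate1_fastq, expected_mate2_fastq)``.  The
    expectation includes only templates whose two mates are both present as
    primary records, with reverse-flagged mates restored to sequencing
    orientation — the independent truth for extraction tests.
    """
    rng = random.Random(seed)
    ref_len = 100_000
    header = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"
    sam_lines: list[str] = []
    exp1: list[str] = []
    exp2: list[str] = []
    pos = 1

    for tpl in templates:
        for flags in (tpl.flags1, tpl.flags2):
            if flags & FLAG_READ1 and flags & FLAG_READ2:
                raise FixtureSpecError(
                    f"template {tpl.name}: flags claim both mate slots"
                )
        mates = []
        if tpl.seq1 is not None:
            mates.append((1, tpl.seq1, tpl.flags1 | FLAG_PAIRED | FLAG_READ1))
        if tpl.seq2 is not None:
            mates.append((2, tpl.seq2, tpl.flags2 | FLAG_PAIRED | FLAG_READ2))
        fastq: dict[int, str] = {}
        for mate, seq, flags in mates:
            if any(b not in _BASES for b in seq):
                raise FixtureSpecError(
                    f"template {tpl.name}: sequence must be over ACGT"
                )
            qual = "".join(chr(33 + rng.randint(10, 40)) for _ in seq)
            if flags & FLAG_UNMAPPED:
                rname, p, mapq, cigar = "*", 0, 0, "*"
            else:
                rname, p, mapq, cigar = "chr1", pos, 60, f"{len(seq)}M"
                pos = pos % (ref_len - 200) + 7
            sam_lines.append(
                f"{tpl.name}\t{flags}\t{rname}\t{p}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{qual}"
            )
            primary = not (flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))
            if primary:
                if flags & FLAG_REVERSE:
                    read_seq = reverse_complement(seq)
                    read_qual = qual[::-1]
                else:
                    read_seq, read_qual = seq, qual
                fastq[mate] = f"@{tpl.name}\n{read_seq}\n+\n{read_qual}\n"
        if 1 in fastq and 2 in fastq:
            exp1.append(fastq[1])
            exp2.append(fastq[2])
    sam_text = header + "\n".join(sam_lines) + ("\n" if sam_lines else "")
    return sam_text, "".join(exp1), "".join(exp2)
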