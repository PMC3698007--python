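"""Multi-subject SNP aggregation: streaming merge of sorted SOAPsnp streams.

Each subject contributes one coordinate-sorted SNP file per chromosome.  The
merge is a k-way merge-sort: it holds exactly one head record per input
stream, repeatedly emits the smallest position present in any stream, and
therefore uses memory proportional to the number of subjects, never to file
length.  At each emitted position every subject's cell is either its decoded
two-allele genotype (e.g. ``"AG"``, ``"CC"``) — if it has a record there
that passes the quality filter and decodes to a concrete diploid genotype —
or a missing code.  A position is emitted only when at least one subject
contributes a passing genotype.

The result is a set of chromosome-based genotype matrix files (one row per
SNP marker, one column per subject, columns in manifest order) suitable as
input to downstream association tools, plus per-subject tallies of the
homozygous / heterozygous / two-alternate-allele (het2) classes.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from .errors import ConsistencyError, ValidationError
from .manifest import MasterManifest, Stage, derive_artifact_name
from .soapsnp import (
    DuplicatePolicy,
    FilterCriteria,
    GenotypeClass,
    SnpRecord,
    UndecodableGenotypeError,
    classify_genotype,
    iupac_to_diploid,
    passes_filter,
    read_sorted_snp_stream,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeRow:
    """One merged marker: position, reference base, one cell per sample."""

    chrom: str
    pos: int
    ref_base: str
    genotype_codes: tuple[str, ...]


@dataclass(frozen=True)
class ClassCounts:
    """Per-subject SNP class tallies (reference-matching sites are not SNPs)."""

    homozygous: int = 0
    heterozygous: int = 0
    het2: int = 0

    @property
    def total(self) -> int:
        return self.homozygous + self.heterozygous + self.het2

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            self.homozygous + other.homozygous,
            self.heterozygous + other.heterozygous,
            self.het2 + other.het2,
        )


@dataclass(frozen=True)
class MergeConfig:
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    missing_code: str = "NN"
    on_duplicate: DuplicatePolicy = DuplicatePolicy.ERROR

    def __post_init__(self) -> None:
        if not self.missing_code or "\t" in self.missing_code:
            raise ValidationError("missing_code must be non-empty and tab-free")
        object.__setattr__(self, "on_duplicate", DuplicatePolicy(self.on_duplicate))


def genotype_code(record: SnpRecord) -> str:
    """Two-character, alphabetically sorted allele string for a record."""
    a, b = sorted(iupac_to_diploid(record.consensus))
    return a + b


def merge_sorted_streams(
    streams: Sequence[Iterable[SnpRecord]],
    sample_ids: Sequence[str],
    config: MergeConfig | None = None,
    on_passing: Callable[[int, SnpRecord, GenotypeClass], None] | None = None,
) -> Iterator[GenotypeRow]:
    """K-way merge of per-sample sorted SNP streams into genotype rows.

    Holds at most one current record per stream.  Rows come out in strictly
    increasing position; a row exists wherever at least one sample has a
    passing, decodable record.  Reference-base disagreement between samples
    at one position is an error (it indicates mixed reference builds).

    ``on_passing(sample_index, record, cls)`` is invoked for every passing
    decodable record, letting callers tally class counts in the same pass.
    """
    if len(streams) != len(sample_ids):
        raise ValidationError(
            f"{len(streams)} streams but {len(sample_ids)} sample ids"
        )
    config = config or MergeConfig()
    n = len(streams)
    iterators = [iter(s) for s in streams]

    heap: list[tuple[int, int, SnpRecord]] = []
    for i, it in enumerate(iterators):
        rec = next(it, None)
        if rec is not None:
            heap.append((rec.pos, i, rec))
    heapq.heapify(heap)

    undecodable = 0
    while heap:
        pos = heap[0][0]
        group: list[tuple[int, SnpRecord]] = []
        while heap and heap[0][0] == pos:
            _, i, rec = heapq.heappop(heap)
            group.append((i, rec))
            nxt = next(iterators[i], None)
            if nxt is not None:
                heapq.heappush(heap, (nxt.pos, i, nxt))

        chrom = group[0][1].chrom
        ref = group[0][1].ref_base
        for _, rec in group[1:]:
            if rec.ref_base != ref:
                raise ConsistencyError(
                    f"conflicting reference bases at pos {pos}: "
                    f"{ref!r} vs {rec.ref_base!r}"
                )

        codes = [config.missing_code] * n
        any_passing = False
        for i, rec in group:
            if not passes_filter(rec, config.criteria):
                continue
            try:
                code = genotype_code(rec)
            except UndecodableGenotypeError:
                undecodable += 1
                continue
            codes[i] = code
            any_passing = True
            if on_passing is not None:
                cls = classify_genotype(iupac_to_diploid(rec.consensus), ref)
                on_passing(i, rec, cls)
        if any_passing:
            yield GenotypeRow(
                chrom=chrom, pos=pos, ref_base=ref, genotype_codes=tuple(codes)
            )
    if undecodable:
        logger.info("dropped %d undecodable consensus call(s)", undecodable)


def summarize_class_counts(
    stream: Iterable[SnpRecord],
    criteria: FilterCriteria | None = None,
) -> ClassCounts:
    """Tally SNP classes over one subject's passing, decodable records.

    Sites whose genotype matches the reference are not SNPs and are not
    counted; the total is by construction the sum of the three SNP classes.
    """
    criteria = criteria or FilterCriteria()
    homo = het = het2 = 0
    undecodable = 0
    for rec in stream:
        if not passes_filter(rec, criteria):
            continue
        try:
            pair = iupac_to_diploid(rec.consensus)
        except UndecodableGenotypeError:
            undecodable += 1
            continue
        cls = classify_genotype(pair, rec.ref_base)
        if cls is GenotypeClass.HOMOZYGOUS:
            homo += 1
        elif cls is GenotypeClass.HETEROZYGOUS:
            het += 1
        elif cls is GenotypeClass.HET2:
            het2 += 1
    if undecodable:
        logger.info("summary dropped %d undecodable record(s)", undecodable)
    return ClassCounts(homozygous=homo, heterozygous=het, het2=het2)


GENOTYPE_HEADER_PREFIX = "#chrom\tpos\tref"


def write_genotype_files(
    rows: Iterable[GenotypeRow],
    sample_ids: Sequence[str],
    output_prefix: str | Path,
) -> list[str]:
    """Write genotype rows to one tab-separated text file per chromosome.

    Rows must arrive grouped by chromosome and sorted within each group.
    Each file starts with ``#chrom  pos  ref  <sample ids in manifest order>``.
    Returns the written file names in order of first appearance.
    """
    out_dir = Path(output_prefix)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = GENOTYPE_HEADER_PREFIX + "".join(f"\t{s}" for s in sample_ids) + "\n"

    written: list[str] = []
    handle = None
    current: str | None = None
    try:
        for row in rows:
            if len(row.genotype_codes) != len(sample_ids):
                raise ValidationError(
                    f"row at {row.chrom}:{row.pos} has {len(row.genotype_codes)} "
                    f"cells for {len(sample_ids)} samples"
                )
            if row.chrom != current:
                if handle is not None:
                    handle.close()
                name = derive_artifact_name(
                    row.chrom, Stage.GENOTYPE, extension="txt"
                )
                if name in written:
                    raise ValidationError(
                        f"rows for chromosome {row.chrom} are not contiguous"
                    )
                written.append(name)
                handle = open(out_dir / name, "wt")
                handle.write(header)
                current = row.chrom
            handle.write(
                f"{row.chrom}\t{row.pos}\t{row.ref_base}\t"
                + "\t".join(row.genotype_codes)
                + "\n"
            )
    finally:
        if handle is not None:
            handle.close()
    return written


def read_genotype_file(path: str | Path) -> tuple[list[str], list[GenotypeRow]]:
    """Parse a genotype matrix file back into sample ids and rows."""
    rows: list[GenotypeRow] = []
    with open(path, "rt") as handle:
        header = handle.readline().rstrip("\n")
        if not header.startswith(GENOTYPE_HEADER_PREFIX):
            raise ValidationError(f"{path}: missing genotype header")
        sample_ids = header.split("\t")[3:]
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            rows.append(
                GenotypeRow(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    ref_base=fields[2],
                    genotype_codes=tuple(fields[3:]),
                )
            )
    return sample_ids, rows


def write_class_summary(
    counts: dict[str, ClassCounts], path: str | Path
) -> None:
    """Write the per-subject class-count table as TSV."""
    with open(path, "wt") as handle:
        handle.write("#subject\thomozygous\theterozygous\thet2\ttotal\n")
        for subject, c in counts.items():
            handle.write(
                f"{subject}\t{c.homozygous}\t{c.heterozygous}\t{c.het2}\t{c.total}\n"
            )


def write_plink_transposed(
    rows: Iterable[GenotypeRow],
    sample_ids: Sequence[str],
    out_path: str | Path,
    missing_code: str = "NN",
) -> int:
    """Export rows in a transposed, association-tool-friendly layout.

    One line per marker: ``chrom  marker-id  0  pos  a1 a2  a1 a2 ...`` with
    alleles space-separated per sample and ``0 0`` for missing cells — the
    transposed-pedigree text convention.  Returns the number of markers.
    """
    n = 0
    with open(out_path, "wt") as handle:
        for row in rows:
            marker = f"{row.chrom}:{row.pos}"
            cells = []
            for code in row.genotype_codes:
                if code == missing_code or len(code) != 2:
                    cells.append("0 0")
                else:
                    cells.append(f"{code[0]} {code[1]}")
            handle.write(
                f"{row.chrom}\t{marker}\t0\t{row.pos}\t" + "\t".join(cells) + "\n"
            )
            n += 1
    return n


@dataclass
class MergeOutcome:
    genotype_files: list[str]
    class_counts: dict[str, ClassCounts]


def merge_subjects(
    manifest: MasterManifest,
    snp_locator_resolver: Callable[[str, str], object | None],
    chromosomes: Sequence[str],
    config: MergeConfig | None = None,
    output_dir: str | Path = ".",
    missing_source: str = "skip",
) -> MergeOutcome:
    """Merge every subject's per-chromosome SNP files into genotype matrices.

    ``snp_locator_resolver(subject_id, chrom)`` returns a readable sorted
    SOAPsnp source (path, handle, or record iterable) or ``None`` when the
    subject has no file for that chromosome.  Under the default policy a
    missing source contributes only missing codes; ``missing_source="error"``
    raises instead.  Class counts are tallied during the same pass as the
    merge, summed across chromosomes.
    """
    config = config or MergeConfig()
    if missing_source not in ("skip", "error"):
        raise ValidationError("missing_source must be 'skip' or 'error'")
    sample_ids = list(manifest.subject_ids)
    tallies: dict[str, ClassCounts] = {s: ClassCounts() for s in sample_ids}

    def rows_for_all() -> Iterator[GenotypeRow]:
        for chrom in chromosomes:
            streams: list[Iterable[SnpRecord]] = []
            for subject in sample_ids:
                source = snp_locator_resolver(subject, chrom)
                if source is None:
                    if missing_source == "error":
                        raise ValidationError(
                            f"no SNP source for subject {subject}, {chrom}"
                        )
                    streams.append(iter(()))
                else:
                    streams.append(
                        read_sorted_snp_stream(
                            source, on_duplicate=config.on_duplicate
                        )
                    )

            def tally(i: int, rec: SnpRecord, cls: GenotypeClass) -> None:
                inc = ClassCounts(
                    homozygous=int(cls is GenotypeClass.HOMOZYGOUS),
                    heterozygous=int(cls is GenotypeClass.HETEROZYGOUS),
                    het2=int(cls is GenotypeClass.HET2),
                )
                tallies[sample_ids[i]] = tallies[sample_ids[i]] + inc

            yield from merge_sorted_streams(
                streams, sample_ids, config, on_passing=tally
            )

    files = write_genotype_files(rows_for_all(), sample_ids, output_dir)
    return MergeOutcome(genotype_files=files, class_counts=tallies)
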