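"""SOAPsnp-format SNP records: parsing, quality filtering, classification.

The SOAPsnp consensus caller emits one coordinate-sorted, tab-separated text
file per chromosome, one SNP per line.  The fields of interest here are the
coordinate, the subject's consensus genotype (a single IUPAC code), the
Phred-scaled genotype quality Q = -10*log10(P_error), and the read support
for the best and second-best bases at the site.

A *quality SNP*, the only kind that survives into the multi-sample merge, is
one whose genotype quality exceeds the threshold implied by a confidence
level (Q > floor(-10*log10(1-confidence)); 95% gives 13, so the smallest
passing quality is 14, i.e. >= 96.0% confidence) and whose best and
second-best bases are each corroborated by at least ``min_unique_reads``
uniquely aligned reads.  The second-base read requirement can optionally be
restricted to heterozygous calls, since a clean homozygous site has no real
second allele.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import (
    DuplicatePositionError,
    SnpParseError,
    SortednessError,
    UndecodableGenotypeError,
    ValidationError,
)

#: Canonical 17-column SOAPsnp output layout (0-based column indices).
DEFAULT_COLUMN_MAP: dict[str, int] = {
    "chrom": 0,
    "pos": 1,
    "ref_base": 2,
    "consensus": 3,
    "quality": 4,
    "best_base": 5,
    "best_avg_qual": 6,
    "best_unique_count": 7,
    "best_all_count": 8,
    "second_base": 9,
    "second_avg_qual": 10,
    "second_unique_count": 11,
    "second_all_count": 12,
    "depth": 13,
    "rank_sum": 14,
    "copy_number": 15,
    "dbsnp_flag": 16,
}

DEFAULT_N_COLUMNS = 17

_VALID_REF = frozenset("ACGTN")

#: Two-way IUPAC ambiguity codes and the unordered base pair they encode;
#: A/C/G/T map to homozygous pairs.
IUPAC_DIPLOID: dict[str, tuple[str, str]] = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}


class GenotypeClass(str, Enum):
    """Site classification of a diploid genotype against the reference base."""

    REFERENCE = "reference"      # both alleles match the reference
    HOMOZYGOUS = "homozygous"    # both alleles equal, non-reference
    HETEROZYGOUS = "heterozygous"  # one reference allele, one alternate
    HET2 = "het2"                # two distinct alleles, neither the reference


class SecondBaseRule(str, Enum):
    """Scope of the second-best-base read-support requirement."""

    BOTH_BASES = "both_bases"  # required for every record
    HET_ONLY = "het_only"      # required only for heterozygous genotypes


class DuplicatePolicy(str, Enum):
    ERROR = "error"
    KEEP_FIRST = "keep_first"


@dataclass(frozen=True)
class SnpRecord:
    """One parsed SOAPsnp line."""

    chrom: str
    pos: int
    ref_base: str
    consensus: str
    quality: int
    best_base: str
    best_unique_count: int
    best_all_count: int
    second_base: str
    second_unique_count: int
    second_all_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.quality < 0:
            raise ValidationError(f"quality must be >= 0, got {self.quality}")
        if self.ref_base not in _VALID_REF:
            raise ValidationError(f"invalid reference base {self.ref_base!r}")
        for label, uniq, total in (
            ("best", self.best_unique_count, self.best_all_count),
            ("second", self.second_unique_count, self.second_all_count),
        ):
            if uniq < 0 or total < uniq:
                raise ValidationError(
                    f"{label}-base counts inconsistent: unique={uniq} all={total}"
                )
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")


def quality_threshold(confidence: float) -> int:
    """Phred quality cutoff for a genotype-confidence level.

    Returns ``floor(-10*log10(1-confidence))``; a record is accepted only if
    its quality is *strictly greater* than this value, which guarantees
    1 - 10**(-Q/10) >= confidence for every accepted record.
    """
    if not (0.0 < confidence < 1.0):
        raise ValidationError(
            f"confidence must lie strictly in (0, 1), got {confidence}"
        )
    # nudge before flooring so exact Phred values (10, 20, ...) survive the
    # float representation of 1-confidence
    return math.floor(-10.0 * math.log10(1.0 - confidence) + 1e-9)


@dataclass(frozen=True)
class FilterCriteria:
    """The quality-SNP definition used during merging.

    Defaults encode 95% genotype confidence (quality strictly above 13) and
    at least two uniquely aligned reads behind both the best and second-best
    bases.
    """

    confidence: float = 0.95
    min_unique_reads: int = 2
    second_base_rule: SecondBaseRule = SecondBaseRule.BOTH_BASES
    quality_cutoff: int = field(init=False)

    def __post_init__(self) -> None:
        if self.min_unique_reads < 0:
            raise ValidationError("min_unique_reads must be >= 0")
        object.__setattr__(
            self, "quality_cutoff", quality_threshold(self.confidence)
        )
        object.__setattr__(
            self, "second_base_rule", SecondBaseRule(self.second_base_rule)
        )


def iupac_to_diploid(consensus: str) -> tuple[str, str]:
    """Decode a single IUPAC consensus code into an unordered allele pair.

    A/C/G/T decode to homozygous pairs; the six two-way ambiguity codes
    decode to heterozygous pairs.  N and the three/four-way codes carry no
    concrete diploid genotype and are rejected.
    """
    try:
        return IUPAC_DIPLOID[consensus.upper()]
    except (KeyError, AttributeError):
        raise UndecodableGenotypeError(
            f"consensus code {consensus!r} does not encode a concrete diploid genotype"
        ) from None


def classify_genotype(genotype: tuple[str, str], ref_base: str) -> GenotypeClass:
    """Classify an allele pair against the reference base.

    The four classes partition all unordered diploid genotypes: reference
    (both alleles reference), homozygous alternate, heterozygous (one
    reference allele), and the rare class with two distinct non-reference
    alleles.
    """
    if ref_base not in "ACGT":
        raise ValidationError(
            f"cannot classify against reference base {ref_base!r}"
        )
    a, b = genotype
    if a == b:
        return GenotypeClass.REFERENCE if a == ref_base else GenotypeClass.HOMOZYGOUS
    if ref_base in (a, b):
        return GenotypeClass.HETEROZYGOUS
    return GenotypeClass.HET2


def passes_filter(record: SnpRecord, criteria: FilterCriteria) -> bool:
    """Apply the quality-SNP criteria to one record."""
    if record.quality <= criteria.quality_cutoff:
        return False
    if record.best_unique_count < criteria.min_unique_reads:
        return False
    if criteria.second_base_rule is SecondBaseRule.BOTH_BASES:
        return record.second_unique_count >= criteria.min_unique_reads
    # het_only: the second-base requirement applies only when the call is
    # actually heterozygous; undecodable codes are held to the stricter rule.
    try:
        a, b = iupac_to_diploid(record.consensus)
    except UndecodableGenotypeError:
        return record.second_unique_count >= criteria.min_unique_reads
    if a != b:
        return record.second_unique_count >= criteria.min_unique_reads
    return True


def _get(fields: list[str], column_map: dict[str, int], key: str, line: str) -> str:
    idx = column_map[key]
    try:
        return fields[idx]
    except IndexError:
        raise SnpParseError(
            f"column {idx} ({key}) missing; line has {len(fields)} fields: {line!r}"
        ) from None


def _int_field(value: str, key: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise SnpParseError(f"non-integer {key} field: {value!r}") from None


def parse_snp_line(
    line: str, column_map: dict[str, int] | None = None
) -> SnpRecord:
    """Parse one tab-separated SOAPsnp line into a :class:`SnpRecord`.

    ``column_map`` maps field names to 0-based column indices; the default
    follows the canonical 17-column SOAPsnp layout.  The line must have
    exactly as many columns as the map's largest index implies.
    """
    cmap = DEFAULT_COLUMN_MAP if column_map is None else column_map
    expected = max(cmap.values()) + 1
    fields = line.rstrip("\n").split("\t")
    if len(fields) != expected:
        raise SnpParseError(
            f"expected {expected} tab-separated fields, got {len(fields)}"
        )
    try:
        return SnpRecord(
            chrom=_get(fields, cmap, "chrom", line),
            pos=_int_field(_get(fields, cmap, "pos", line), "pos"),
            ref_base=_get(fields, cmap, "ref_base", line).upper(),
            consensus=_get(fields, cmap, "consensus", line).upper(),
            quality=_int_field(_get(fields, cmap, "quality", line), "quality"),
            best_base=_get(fields, cmap, "best_base", line).upper(),
            best_unique_count=_int_field(
                _get(fields, cmap, "best_unique_count", line), "best_unique_count"
            ),
            best_all_count=_int_field(
                _get(fields, cmap, "best_all_count", line), "best_all_count"
            ),
            second_base=_get(fields, cmap, "second_base", line).upper(),
            second_unique_count=_int_field(
                _get(fields, cmap, "second_unique_count", line),
                "second_unique_count",
            ),
            second_all_count=_int_field(
                _get(fields, cmap, "second_all_count", line), "second_all_count"
            ),
            depth=_int_field(_get(fields, cmap, "depth", line), "depth"),
        )
    except ValidationError as exc:
        raise SnpParseError(str(exc)) from exc


def serialize_snp_record(record: SnpRecord) -> str:
    """Render a record as a canonical 17-column SOAPsnp line.

    Fields the record does not model (average qualities, rank-sum test,
    copy number, dbSNP flag) are written as neutral placeholders.
    """
    fields = [""] * DEFAULT_N_COLUMNS
    fields[DEFAULT_COLUMN_MAP["chrom"]] = record.chrom
    fields[DEFAULT_COLUMN_MAP["pos"]] = str(record.pos)
    fields[DEFAULT_COLUMN_MAP["ref_base"]] = record.ref_base
    fields[DEFAULT_COLUMN_MAP["consensus"]] = record.consensus
    fields[DEFAULT_COLUMN_MAP["quality"]] = str(record.quality)
    fields[DEFAULT_COLUMN_MAP["best_base"]] = record.best_base
    fields[DEFAULT_COLUMN_MAP["best_avg_qual"]] = "0.0"
    fields[DEFAULT_COLUMN_MAP["best_unique_count"]] = str(record.best_unique_count)
    fields[DEFAULT_COLUMN_MAP["best_all_count"]] = str(record.best_all_count)
    fields[DEFAULT_COLUMN_MAP["second_base"]] = record.second_base
    fields[DEFAULT_COLUMN_MAP["second_avg_qual"]] = "0.0"
    fields[DEFAULT_COLUMN_MAP["second_unique_count"]] = str(
        record.second_unique_count
    )
    fields[DEFAULT_COLUMN_MAP["second_all_count"]] = str(record.second_all_count)
    fields[DEFAULT_COLUMN_MAP["depth"]] = str(record.depth)
    fields[DEFAULT_COLUMN_MAP["rank_sum"]] = "1.0"
    fields[DEFAULT_COLUMN_MAP["copy_number"]] = "1.0"
    fields[DEFAULT_COLUMN_MAP["dbsnp_flag"]] = "0"
    return "\t".join(fields)


def open_snp_source(source: str | Path | IO[str] | Iterable[str]) -> Iterable[str]:
    """Open a SOAPsnp source as an iterable of text lines.

    Accepts a path (plain or ``.gz``), an open text handle, or any iterable
    of lines.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, "rt")
        return open(path, "rt")
    return source


def read_sorted_snp_stream(
    source: str | Path | IO[str] | Iterable[str],
    column_map: dict[str, int] | None = None,
    on_duplicate: DuplicatePolicy | str = DuplicatePolicy.ERROR,
) -> Iterator[SnpRecord]:
    """Stream records from one chromosome's file, enforcing sort order.

    Yields records in strictly increasing position, checking monotonicity on
    the fly without ever materializing the file.  Duplicate positions either
    raise or keep the first record, per ``on_duplicate``.
    """
    on_duplicate = DuplicatePolicy(on_duplicate)
    lines = open_snp_source(source)
    last_pos: int | None = None
    try:
        for idx, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                record = parse_snp_line(line, column_map)
            except SnpParseError as exc:
                raise SnpParseError(f"record {idx}: {exc}") from exc
            if last_pos is not None:
                if record.pos == last_pos:
                    if on_duplicate is DuplicatePolicy.ERROR:
                        raise DuplicatePositionError(
                            f"duplicate position {record.pos} at record {idx}"
                        )
                    continue
                if record.pos < last_pos:
                    raise SortednessError(
                        f"positions out of order: {last_pos} followed by {record.pos}"
                    )
            last_pos = record.pos
            yield record
    finally:
        closer = getattr(lines, "close", None)
        if closer is not None and lines is not source:
            closer()
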