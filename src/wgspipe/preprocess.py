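"""Raw-read pre-processing: alignment extraction and paired-FASTQ splitting.

Sequencing providers deliver raw reads either as paired FASTQ files or as
BAM/SAM (already aligned).  Downstream re-alignment consumes paired FASTQ in
chunks of bounded size, so this module provides

* :func:`extract_reads_from_alignment` — recover the original paired reads
  from SAM/BAM, undoing the reverse-complement storage of reverse-strand
  alignments and ignoring secondary/supplementary copies;
* :func:`split_fastq_pair` — cut a FASTQ pair into mate-synchronized chunks
  whose concatenation is byte-identical to the input;
* :func:`write_chunk_manifest` — describe the chunks (with optional MD5
  checksums) in the tab-separated paired format the alignment stage reads.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Callable, Iterator

import pysam

from .errors import (
    ExtractionError,
    FastqParseError,
    SynchronizationError,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SingletonPolicy(str, Enum):
    """What to do with reads whose mate never appears as a primary record."""

    ERROR = "error"
    SEPARATE_FILE = "separate_file"
    DROP = "drop"


@dataclass(frozen=True)
class ExtractionResult:
    """Tallies from one alignment-to-FASTQ extraction."""

    paired_templates: int
    singletons: int
    excluded_records: int


@dataclass(frozen=True)
class SplitPlan:
    """How to chunk a FASTQ pair: reads per chunk per mate, and compression."""

    chunk_reads: int = 4_000_000
    compress_output: bool = True

    def __post_init__(self) -> None:
        if self.chunk_reads < 1:
            raise ValidationError("chunk_reads must be >= 1")


@dataclass(frozen=True)
class SplitResult:
    mate1_chunks: tuple[str, ...]
    mate2_chunks: tuple[str, ...]
    reads_per_chunk: tuple[int, ...]
    total_read_pairs: int

    def __post_init__(self) -> None:
        if not (
            len(self.mate1_chunks)
            == len(self.mate2_chunks)
            == len(self.reads_per_chunk)
        ):
            raise ValidationError("chunk lists must have equal length")
        if sum(self.reads_per_chunk) != self.total_read_pairs:
            raise ValidationError("reads_per_chunk must sum to total_read_pairs")


def _fastq_record_text(name: str, seq: str, qual: str) -> str:
    return f"@{name}\n{seq}\n+\n{qual}\n"


def extract_reads_from_alignment(
    alignment_source: str | Path | pysam.AlignmentFile,
    out_mate1: IO[str],
    out_mate2: IO[str],
    singleton_policy: SingletonPolicy | str = SingletonPolicy.DROP,
    singleton_sink: IO[str] | None = None,
    drop_duplicates: bool = False,
) -> ExtractionResult:
    """Recover the original paired reads from a SAM/BAM source.

    Templates are paired by name; SAM flag bits 0x40/0x80 assign the mate
    slot.  A record stored reverse-complemented (flag 0x10) is flipped back
    to sequencing orientation (sequence reverse-complemented, quality string
    reversed).  Secondary (0x100) and supplementary (0x800) records never
    carry new raw reads and are excluded; unmapped primaries are extracted
    because they do.  Memory is bounded by the number of templates whose
    mate has not yet been seen, not by file size.
    """
    policy = SingletonPolicy(singleton_policy)
    if policy is SingletonPolicy.SEPARATE_FILE and singleton_sink is None:
        raise ValidationError("singleton_policy=separate_file needs singleton_sink")

    own_handle = False
    if isinstance(alignment_source, (str, Path)):
        alignment_source = pysam.AlignmentFile(
            str(alignment_source), check_sq=False
        )
        own_handle = True

    pending: dict[str, tuple[int, str]] = {}  # name -> (mate slot, fastq text)
    paired = singletons = excluded = 0
    try:
        for rec in alignment_source.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                excluded += 1
                continue
            if drop_duplicates and rec.is_duplicate:
                excluded += 1
                continue
            name = rec.query_name
            seq = rec.query_sequence
            if name is None or seq is None:
                raise ExtractionError(
                    f"record without name or sequence: {rec.to_string()!r}"
                )
            qual = (
                "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else "I" * len(seq)
            )
            if rec.is_reverse:
                seq = reverse_complement(seq)
                qual = qual[::-1]
            if rec.is_read2:
                slot = 2
            else:
                slot = 1  # read1 flag, or unpaired record
            text = _fastq_record_text(name, seq, qual)
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = (slot, text)
                continue
            prev_slot, prev_text = mate
            if prev_slot == slot:
                raise ExtractionError(
                    f"template {name!r}: two primary records in mate slot {slot}"
                )
            first, second = (
                (prev_text, text) if prev_slot == 1 else (text, prev_text)
            )
            out_mate1.write(first)
            out_mate2.write(second)
            paired += 1
    finally:
        if own_handle:
            alignment_source.close()

    if pending:
        if policy is SingletonPolicy.ERROR:
            names = ", ".join(sorted(pending)[:5])
            raise ExtractionError(
                f"{len(pending)} singleton template(s), e.g. {names}"
            )
        singletons = len(pending)
        if policy is SingletonPolicy.SEPARATE_FILE:
            assert singleton_sink is not None
            for name in sorted(pending):
                singleton_sink.write(pending[name][1])
    return ExtractionResult(
        paired_templates=paired, singletons=singletons, excluded_records=excluded
    )


def _read_fastq_record(stream: IO[str], ordinal: int) -> tuple[str, ...] | None:
    """Read one raw 4-line record; None at clean EOF."""
    header = stream.readline()
    if header == "":
        return None
    rest = (stream.readline(), stream.readline(), stream.readline())
    if any(line == "" for line in rest):
        raise FastqParseError(f"truncated record at ordinal {ordinal}")
    if not header.startswith("@") or not rest[1].startswith("+"):
        raise FastqParseError(f"malformed record at ordinal {ordinal}")
    return (header,) + rest


def template_name(fastq_header: str) -> str:
    """Template name from a FASTQ header: strip '@', comment, and /1 /2."""
    name = fastq_header[1:].split()[0] if len(fastq_header) > 1 else ""
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def split_fastq_pair(
    mate1: IO[str],
    mate2: IO[str],
    plan: SplitPlan,
    name_for_chunk: Callable[[int, int], str],
    out_dir: str | Path = ".",
) -> SplitResult:
    """Split a FASTQ pair into mate-synchronized chunks.

    Chunk i of each mate holds the same templates at the same ordinals, and
    concatenating a mate's chunks reproduces that mate's input record for
    record.  ``name_for_chunk(mate, index)`` names each chunk file; files
    are written under ``out_dir``, gzip-compressed when the plan says so.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mate1_chunks: list[str] = []
    mate2_chunks: list[str] = []
    reads_per_chunk: list[int] = []
    total = 0

    def _open(name: str) -> IO[str]:
        path = out_dir / name
        if plan.compress_output:
            return gzip.open(path, "wt")
        return open(path, "wt")

    sink1 = sink2 = None
    in_chunk = 0
    try:
        while True:
            rec1 = _read_fastq_record(mate1, total)
            rec2 = _read_fastq_record(mate2, total)
            if rec1 is None or rec2 is None:
                if rec1 is not None or rec2 is not None:
                    longer = "mate1" if rec2 is None else "mate2"
                    raise SynchronizationError(
                        f"unequal read counts: {longer} continues past "
                        f"{total} shared read pair(s)"
                    )
                break
            if template_name(rec1[0].rstrip()) != template_name(rec2[0].rstrip()):
                raise SynchronizationError(
                    f"template mismatch at ordinal {total}: "
                    f"{rec1[0].strip()!r} vs {rec2[0].strip()!r}"
                )
            if sink1 is None:
                idx = len(mate1_chunks)
                mate1_chunks.append(name_for_chunk(1, idx))
                mate2_chunks.append(name_for_chunk(2, idx))
                sink1 = _open(mate1_chunks[-1])
                sink2 = _open(mate2_chunks[-1])
                in_chunk = 0
            sink1.write("".join(rec1))
            sink2.write("".join(rec2))
            in_chunk += 1
            total += 1
            if in_chunk == plan.chunk_reads:
                sink1.close()
                sink2.close()
                sink1 = sink2 = None
                reads_per_chunk.append(in_chunk)
        if sink1 is not None:
            sink1.close()
            sink2.close()
            reads_per_chunk.append(in_chunk)
    except Exception:
        if sink1 is not None:
            sink1.close()
        if sink2 is not None:
            sink2.close()
        raise
    return SplitResult(
        mate1_chunks=tuple(mate1_chunks),
        mate2_chunks=tuple(mate2_chunks),
        reads_per_chunk=tuple(reads_per_chunk),
        total_read_pairs=total,
    )


def md5_of_file(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def write_chunk_manifest(
    result: SplitResult,
    locator_prefix: str,
    include_checksums: bool = False,
    chunk_dir: str | Path = ".",
) -> str:
    """Render the chunk manifest consumed by the alignment stage.

    One line per chunk pair, four tab-separated fields:
    ``<prefix>/<mate1 chunk>  <md5|0>  <prefix>/<mate2 chunk>  <md5|0>``.
    """
    if not result.mate1_chunks:
        raise ValidationError("empty split result: nothing to align")
    prefix = locator_prefix.rstrip("/")
    chunk_dir = Path(chunk_dir)
    lines = []
    for c1, c2 in zip(result.mate1_chunks, result.mate2_chunks):
        if include_checksums:
            sum1 = md5_of_file(chunk_dir / c1)
            sum2 = md5_of_file(chunk_dir / c2)
        else:
            sum1 = sum2 = "0"
        lines.append(f"{prefix}/{c1}\t{sum1}\t{prefix}/{c2}\t{sum2}")
    return "\n".join(lines) + "\n"


def iter_fastq_records(stream: IO[str]) -> Iterator[tuple[str, str, str, str]]:
    """Iterate raw 4-line FASTQ records (lines keep their newlines)."""
    ordinal = 0
    while True:
        rec = _read_fastq_record(stream, ordinal)
        if rec is None:
            return
        yield rec
        ordinal += 1
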