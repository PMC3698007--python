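"""Master manifest parsing and the deterministic artifact-naming convention.

A whole-genome sequencing project is driven by a single plain-text *master
manifest*: one line per subject, three whitespace-separated fields —

    <subject_id>   <raw read locator(s)>   <output prefix>

The raw reads are either a single ``.bam`` locator or two FASTQ locators
(mate 1 then mate 2) joined by ``;``.  Record order is significant: it fixes
the sample-column order of every downstream genotype matrix.  The subject id
plus a fixed naming scheme determine the name of every intermediate and
result file, so distinct subjects can never collide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable

from .errors import ManifestParseError, ValidationError

_SUBJECT_ID_RE = re.compile(r"[A-Za-z0-9_.-]+\Z")
_FASTQ_RE = re.compile(r"\.(fastq|fq)(\.gz)?\Z", re.IGNORECASE)
_BAM_RE = re.compile(r"\.(bam|sam)\Z", re.IGNORECASE)


class InputKind(str, Enum):
    """How a subject's raw reads are delivered."""

    BAM = "bam"
    FASTQ_PAIR = "fastq_pair"


class Stage(str, Enum):
    """Pipeline stages that produce named artifacts."""

    EXTRACT = "extract"
    SPLIT = "split"
    SNP = "snp"
    GENOTYPE = "genotype"


#: Stages whose artifacts are per-mate files.
_PAIRED_STAGES = frozenset({Stage.EXTRACT, Stage.SPLIT})


@dataclass(frozen=True)
class SubjectRecord:
    """One manifest entry: a subject and where its data lives."""

    subject_id: str
    input_kind: InputKind
    inputs: tuple[str, ...]
    output_prefix: str

    def __post_init__(self) -> None:
        if not _SUBJECT_ID_RE.match(self.subject_id):
            raise ValidationError(
                f"invalid subject id {self.subject_id!r}: must match [A-Za-z0-9_.-]+"
            )
        expected = 1 if self.input_kind is InputKind.BAM else 2
        if len(self.inputs) != expected:
            raise ValidationError(
                f"subject {self.subject_id}: {self.input_kind.value} needs "
                f"{expected} input locator(s), got {len(self.inputs)}"
            )
        if any(not loc for loc in self.inputs) or not self.output_prefix:
            raise ValidationError(
                f"subject {self.subject_id}: empty locator"
            )


@dataclass(frozen=True)
class MasterManifest:
    """All subjects of a project, in file order."""

    records: tuple[SubjectRecord, ...]
    source_name: str = "<string>"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValidationError(f"duplicate subject id {rec.subject_id!r}")
            seen.add(rec.subject_id)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(r.subject_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, subject_id: str) -> SubjectRecord:
        for rec in self.records:
            if rec.subject_id == subject_id:
                return rec
        raise KeyError(subject_id)


def _classify_inputs(raw: str, lineno: int) -> tuple[InputKind, tuple[str, ...]]:
    parts = [p.strip() for p in raw.split(";")]
    parts = [p for p in parts if p]
    if len(parts) == 1:
        loc = parts[0]
        if _BAM_RE.search(loc):
            return InputKind.BAM, (loc,)
        if _FASTQ_RE.search(loc):
            raise ManifestParseError(
                f"line {lineno}: single FASTQ locator {loc!r}; paired FASTQ "
                "requires two ';'-separated locators"
            )
        raise ManifestParseError(
            f"line {lineno}: unrecognized input extension in {loc!r}"
        )
    if len(parts) == 2:
        for loc in parts:
            if not _FASTQ_RE.search(loc):
                raise ManifestParseError(
                    f"line {lineno}: unrecognized FASTQ extension in {loc!r}"
                )
        return InputKind.FASTQ_PAIR, tuple(parts)
    raise ManifestParseError(
        f"line {lineno}: expected 1 or 2 ';'-separated read locators, got {len(parts)}"
    )


def parse_master_manifest(text: str, source_name: str = "<string>") -> MasterManifest:
    """Parse manifest text into a :class:`MasterManifest`.

    Fields are separated by runs of spaces and/or tabs; because FASTQ pair
    locators may contain "; " the second field is recovered as everything
    between the first and the last field.  Blank lines and lines starting
    with ``#`` are skipped.
    """
    records: list[SubjectRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < 3:
            raise ManifestParseError(
                f"line {lineno}: expected 3 whitespace-separated fields, got {len(tokens)}"
            )
        subject_id = tokens[0]
        output_prefix = tokens[-1]
        middle = " ".join(tokens[1:-1])
        if ";" not in middle and len(tokens) != 3:
            raise ManifestParseError(
                f"line {lineno}: expected 3 fields, got {len(tokens)}"
            )
        try:
            kind, inputs = _classify_inputs(middle, lineno)
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    input_kind=kind,
                    inputs=inputs,
                    output_prefix=output_prefix,
                )
            )
        except ValidationError as exc:
            if isinstance(exc, ManifestParseError):
                raise
            raise ManifestParseError(f"line {lineno}: {exc}") from exc
    manifest = MasterManifest(records=tuple(records), source_name=source_name)
    return manifest


def serialize_manifest(manifest: MasterManifest) -> str:
    """Render a manifest back to its canonical text form."""
    lines = []
    for rec in manifest.records:
        middle = "; ".join(rec.inputs)
        lines.append(f"{rec.subject_id}\t{middle}\t{rec.output_prefix}")
    return "\n".join(lines) + ("\n" if lines else "")


def derive_artifact_name(
    subject_id: str,
    stage: Stage | str,
    mate: int | None = None,
    chunk_index: int | None = None,
    extension: str = "txt",
) -> str:
    """Deterministic, collision-free artifact file name.

    Scheme: ``<subject_id>.<stage>[_<mate>][.<chunk, zero-padded to 4>].<ext>``.
    """
    stage = Stage(stage)
    if not _SUBJECT_ID_RE.match(subject_id):
        raise ValidationError(f"invalid subject id {subject_id!r}")
    if mate is not None:
        if stage not in _PAIRED_STAGES:
            raise ValidationError(
                f"stage {stage.value!r} has no per-mate artifacts"
            )
        if mate not in (1, 2):
            raise ValidationError(f"mate must be 1 or 2, got {mate}")
    if chunk_index is not None and chunk_index < 0:
        raise ValidationError(f"chunk_index must be >= 0, got {chunk_index}")
    name = f"{subject_id}.{stage.value}"
    if mate is not None:
        name += f"_{mate}"
    if chunk_index is not None:
        name += f".{chunk_index:04d}"
    return f"{name}.{extension}"


@dataclass(frozen=True)
class RecordCheck:
    """Outcome of checking one manifest record's inputs."""

    subject_id: str
    ok: bool
    missing: tuple[str, ...] = field(default=())

    @property
    def reason(self) -> str:
        return "" if self.ok else "missing: " + ", ".join(self.missing)


def validate_manifest(
    manifest: MasterManifest,
    existence_checker: Callable[[str], bool],
) -> list[RecordCheck]:
    """Check every record's input locators against an existence predicate.

    Failures are reported, never raised; the manifest is not modified.
    """
    report: list[RecordCheck] = []
    for rec in manifest.records:
        missing = tuple(loc for loc in rec.inputs if not existence_checker(loc))
        report.append(
            RecordCheck(subject_id=rec.subject_id, ok=not missing, missing=missing)
        )
    return report


def failed_checks(report: Iterable[RecordCheck]) -> list[RecordCheck]:
    return [c for c in report if not c.ok]
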