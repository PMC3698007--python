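"""Stage orchestration: wire manifest, preprocessing, merge, and metrics.

The pipeline has four conceptual steps; alignment and SNP calling are
performed by external tools and are represented here only by a directory
contract: the merge stage consumes whatever coordinate-sorted SOAPsnp files
appear under ``<workdir>/<subject>/snp/<chrom>.txt[.gz]`` (an external
caller or the fixtures module populates them).  This module implements the
two locally-computable stages — per-subject preprocessing (extraction +
splitting + chunk manifest) and the multi-subject merge — recording one
metric line per step.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

from .errors import ValidationError
from .manifest import (
    InputKind,
    MasterManifest,
    Stage,
    SubjectRecord,
    derive_artifact_name,
)
from .merge import MergeConfig, MergeOutcome, merge_subjects, write_class_summary
from .metrics import MetricRecord, RetryPolicy, Step, record_metric, with_retry
from .preprocess import (
    ExtractionResult,
    SingletonPolicy,
    SplitPlan,
    SplitResult,
    extract_reads_from_alignment,
    split_fastq_pair,
    write_chunk_manifest,
)


@dataclass
class PipelineConfig:
    manifest: MasterManifest
    workdir: Path
    split_plan: SplitPlan = field(default_factory=SplitPlan)
    merge_config: MergeConfig = field(default_factory=MergeConfig)
    retry_policy: RetryPolicy = field(default_factory=RetryPolicy)
    chromosomes: tuple[str, ...] = ("chr1",)
    metrics_sink: IO[str] | None = None
    include_checksums: bool = True
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)


def _open_reads(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _record(config: PipelineConfig, rec: MetricRecord) -> None:
    if config.metrics_sink is not None:
        record_metric(config.metrics_sink, rec)


@dataclass
class PreprocessOutcome:
    subject_id: str
    extraction: ExtractionResult | None
    split: SplitResult
    chunk_manifest_path: Path


def run_preprocess_stage(
    config: PipelineConfig, subject_id: str
) -> PreprocessOutcome:
    """Preprocess one subject: extract (BAM input only), split, manifest.

    FASTQ-pair subjects skip extraction entirely.  All artifacts land in
    ``<workdir>/<subject_id>/`` under the deterministic naming convention.
    """
    record: SubjectRecord = config.manifest.get(subject_id)
    subject_dir = config.workdir / subject_id
    subject_dir.mkdir(parents=True, exist_ok=True)

    extraction: ExtractionResult | None = None
    if record.input_kind is InputKind.BAM:
        ext1 = subject_dir / derive_artifact_name(
            subject_id, Stage.EXTRACT, mate=1, extension="fastq"
        )
        ext2 = subject_dir / derive_artifact_name(
            subject_id, Stage.EXTRACT, mate=2, extension="fastq"
        )

        def do_extract() -> ExtractionResult:
            with open(ext1, "wt") as o1, open(ext2, "wt") as o2:
                return extract_reads_from_alignment(
                    record.inputs[0], o1, o2,
                    singleton_policy=SingletonPolicy.DROP,
                )

        extraction = with_retry(
            do_extract,
            config.retry_policy,
            recorder=lambda m: _record(config, m),
            run_id=config.run_id,
            subject_id=subject_id,
            step=Step.EXTRACT,
        )
        mate1_path, mate2_path = ext1, ext2
    else:
        mate1_path, mate2_path = (Path(p) for p in record.inputs)

    ext = "fastq.gz" if config.split_plan.compress_output else "fastq"

    def name_for_chunk(mate: int, index: int) -> str:
        return derive_artifact_name(
            subject_id, Stage.SPLIT, mate=mate, chunk_index=index, extension=ext
        )

    def do_split() -> SplitResult:
        with _open_reads(mate1_path) as m1, _open_reads(mate2_path) as m2:
            return split_fastq_pair(
                m1, m2, config.split_plan, name_for_chunk, out_dir=subject_dir
            )

    split = with_retry(
        do_split,
        config.retry_policy,
        recorder=lambda m: _record(config, m),
        run_id=config.run_id,
        subject_id=subject_id,
        step=Step.SPLIT,
    )

    manifest_text = write_chunk_manifest(
        split,
        locator_prefix=record.output_prefix,
        include_checksums=config.include_checksums,
        chunk_dir=subject_dir,
    )
    manifest_path = subject_dir / f"{subject_id}.chunks.manifest"
    manifest_path.write_text(manifest_text)
    return PreprocessOutcome(
        subject_id=subject_id,
        extraction=extraction,
        split=split,
        chunk_manifest_path=manifest_path,
    )


def snp_path_resolver(workdir: Path):
    """Resolver for the directory contract <workdir>/<subject>/snp/<chrom>.txt[.gz]."""

    def resolve(subject_id: str, chrom: str):
        base = Path(workdir) / subject_id / "snp"
        for name in (f"{chrom}.txt", f"{chrom}.txt.gz"):
            path = base / name
            if path.exists():
                return path
        return None

    return resolve


def run_merge_stage(
    config: PipelineConfig, output_dir: Path | None = None
) -> MergeOutcome:
    """Merge all subjects' SNP files into genotype matrices + summary table."""
    out = Path(output_dir) if output_dir is not None else config.workdir / "genotypes"

    def do_merge() -> MergeOutcome:
        return merge_subjects(
            config.manifest,
            snp_path_resolver(config.workdir),
            config.chromosomes,
            config.merge_config,
            output_dir=out,
        )

    outcome = with_retry(
        do_merge,
        RetryPolicy(max_attempts=1, wait_seconds=0),
        recorder=lambda m: _record(config, m),
        run_id=config.run_id,
        subject_id="-",
        step=Step.MERGE,
    )
    write_class_summary(outcome.class_counts, out / "class_summary.tsv")
    return outcome
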