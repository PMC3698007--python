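"""Run-metrics logging and retry-on-failure for data transfers.

Large-file transfers fail transiently (network congestion being the usual
culprit), so every transfer-like step runs under :func:`with_retry`: on
failure the step waits a configurable number of seconds and re-runs, up to
``max_attempts`` times.  Every attempt — success, retried failure, or final
failure — is recorded as one :class:`MetricRecord` line in an append-only
TSV log with ISO-8601 timestamps, so a whole run can be reconstructed and
timed from its log alone.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from typing import IO, Callable, TypeVar

from .errors import ValidationError

T = TypeVar("T")


class Step(str, Enum):
    DOWNLOAD = "download"
    EXTRACT = "extract"
    SPLIT = "split"
    UPLOAD = "upload"
    MERGE = "merge"


class Status(str, Enum):
    SUCCESS = "success"
    RETRIED = "retried"   # this attempt failed but another follows
    FAILED = "failed"     # this attempt failed and no retries remain


@dataclass(frozen=True)
class RetryPolicy:
    """Retry up to ``max_attempts`` times, sleeping ``wait_seconds`` between.

    The default 300 s wait sits in the middle of the practical advice of
    waiting several minutes before re-fetching after a transfer failure.
    """

    max_attempts: int = 3
    wait_seconds: float = 300.0

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValidationError("max_attempts must be >= 1")
        if self.wait_seconds < 0:
            raise ValidationError("wait_seconds must be >= 0")


@dataclass(frozen=True)
class MetricRecord:
    run_id: str
    subject_id: str
    step: Step
    started_at: datetime
    ended_at: datetime
    duration_seconds: float
    status: Status
    attempt: int
    bytes_processed: int | None = None

    def __post_init__(self) -> None:
        if self.ended_at < self.started_at:
            raise ValidationError("ended_at must not precede started_at")
        if self.attempt < 1:
            raise ValidationError("attempt numbering is 1-based")
        if self.bytes_processed is not None and self.bytes_processed < 0:
            raise ValidationError("bytes_processed must be >= 0")


_FIELDS = (
    "run_id subject_id step started_at ended_at duration_seconds "
    "status attempt bytes_processed"
).split()


def serialize_metric(record: MetricRecord) -> str:
    """One tab-separated line; absent bytes_processed serializes as empty."""
    values = [
        record.run_id,
        record.subject_id,
        record.step.value,
        record.started_at.isoformat(),
        record.ended_at.isoformat(),
        f"{record.duration_seconds:.6f}",
        record.status.value,
        str(record.attempt),
        "" if record.bytes_processed is None else str(record.bytes_processed),
    ]
    return "\t".join(values)


def parse_metric(line: str) -> MetricRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != len(_FIELDS):
        raise ValidationError(
            f"metric line has {len(fields)} fields, expected {len(_FIELDS)}"
        )
    return MetricRecord(
        run_id=fields[0],
        subject_id=fields[1],
        step=Step(fields[2]),
        started_at=datetime.fromisoformat(fields[3]),
        ended_at=datetime.fromisoformat(fields[4]),
        duration_seconds=float(fields[5]),
        status=Status(fields[6]),
        attempt=int(fields[7]),
        bytes_processed=None if fields[8] == "" else int(fields[8]),
    )


def record_metric(log_sink: IO[str], record: MetricRecord) -> None:
    """Append one whole line per record (line-atomic single write)."""
    log_sink.write(serialize_metric(record) + "\n")
    flush = getattr(log_sink, "flush", None)
    if flush is not None:
        flush()


def read_metrics(lines) -> list[MetricRecord]:
    return [parse_metric(line) for line in lines if line.strip()]


def _now() -> datetime:
    return datetime.now(timezone.utc)


def with_retry(
    action: Callable[[], T],
    policy: RetryPolicy | None = None,
    sleeper: Callable[[float], None] = time.sleep,
    *,
    recorder: Callable[[MetricRecord], None] | None = None,
    run_id: str = "run",
    subject_id: str = "-",
    step: Step = Step.DOWNLOAD,
    clock: Callable[[], datetime] = _now,
) -> T:
    """Run a fallible, safely re-runnable action with fixed-wait retries.

    Returns the first successful result.  Between attempts the injected
    ``sleeper`` is called with ``policy.wait_seconds`` (injection keeps
    tests instant).  If a ``recorder`` is given, one MetricRecord is
    emitted per attempt with 1-based, gapless attempt numbers.  When every
    attempt fails, the final exception is re-raised annotated with the
    attempt count.
    """
    policy = policy or RetryPolicy()
    last_exc: BaseException | None = None
    for attempt in range(1, policy.max_attempts + 1):
        started = clock()
        try:
            result = action()
        except Exception as exc:  # noqa: BLE001 - any failure is retryable
            last_exc = exc
            ended = clock()
            if recorder is not None:
                recorder(
                    MetricRecord(
                        run_id=run_id,
                        subject_id=subject_id,
                        step=step,
                        started_at=started,
                        ended_at=ended,
                        duration_seconds=(ended - started).total_seconds(),
                        status=(
                            Status.RETRIED
                            if attempt < policy.max_attempts
                            else Status.FAILED
                        ),
                        attempt=attempt,
                    )
                )
            if attempt < policy.max_attempts:
                sleeper(policy.wait_seconds)
            continue
        ended = clock()
        if recorder is not None:
            recorder(
                MetricRecord(
                    run_id=run_id,
                    subject_id=subject_id,
                    step=step,
                    started_at=started,
                    ended_at=ended,
                    duration_seconds=(ended - started).total_seconds(),
                    status=Status.SUCCESS,
                    attempt=attempt,
                )
            )
        return result
    assert last_exc is not None
    if hasattr(last_exc, "add_note"):
        last_exc.add_note(f"failed after {policy.max_attempts} attempt(s)")
    raise last_exc
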