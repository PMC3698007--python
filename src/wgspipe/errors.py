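"""Exception hierarchy shared across the pipeline.

Three failure families map onto the CLI exit codes: validation problems
(bad manifests, bad parameters) exit 2, data problems (unsorted or
inconsistent inputs) exit 3, and I/O problems exit 4.
"""

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_DATA = 3
EXIT_IO = 4


class WgspipeError(Exception):
    """Base class for all package errors."""

    exit_code = EXIT_DATA


class ValidationError(WgspipeError):
    """Invalid configuration, manifest, or parameter values."""

    exit_code = EXIT_VALIDATION


class ManifestParseError(ValidationError):
    """Malformed master-manifest text."""


class DataError(WgspipeError):
    """Malformed or inconsistent input data."""

    exit_code = EXIT_DATA


class SnpParseError(DataError):
    """A SOAPsnp line that cannot be parsed or violates field constraints."""


class SortednessError(DataError):
    """A coordinate-sorted stream yielded positions out of order."""


class DuplicatePositionError(DataError):
    """Two records at one position where the policy forbids it."""


class SynchronizationError(DataError):
    """Paired FASTQ streams disagree in length or template names."""


class FastqParseError(DataError):
    """Truncated or malformed 4-line FASTQ record."""


class ExtractionError(DataError):
    """Alignment-to-FASTQ extraction failed (e.g. singleton under policy=error)."""


class ConsistencyError(DataError):
    """Cross-sample disagreement, e.g. conflicting reference bases at one site."""


class UndecodableGenotypeError(DataError):
    """A consensus code that does not decode to a concrete diploid genotype."""


class FixtureSpecError(ValidationError):
    """A synthetic-data specification that cannot be realized exactly."""
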