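"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MirseedError`, so callers (and the
CLI) can distinguish configuration mistakes from malformed data.
"""


class MirseedError(Exception):
    """Base class for all package errors."""


class ConfigError(MirseedError):
    """Invalid parameter or configuration value."""


class MalformedSequenceError(MirseedError):
    """A sequence contains a character outside the accepted alphabet."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position  # 1-based
        super().__init__(
            f"malformed sequence: invalid character {sequence[position - 1]!r} "
            f"at position {position}"
        )


class FastqParseError(MirseedError):
    """A FASTQ record is truncated or internally inconsistent."""

    def __init__(self, message: str, record_index: int | None = None):
        self.record_index = record_index
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)


class ReferenceFormatError(MirseedError):
    """A reference FASTA header cannot be resolved to a species/name."""


class FixtureIntegrityError(MirseedError):
    """A packaged fixture table does not match its manifest."""


class MalformedPatternError(MirseedError):
    """An alignment pattern contains a character outside {A,C,G,U,-}."""


class InvalidOffsetError(MirseedError):
    """An overlay offset leaves the two sequences with no overlap."""


class IncompleteDesignError(MirseedError):
    """A qPCR design is missing the reference assay or calibrator sample."""


class UndefinedCorrelationError(MirseedError):
    """Too few points or zero variance for a correlation coefficient."""


class PipelineError(MirseedError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
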