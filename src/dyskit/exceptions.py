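"""Exception hierarchy shared across the pipeline."""


class DyskitError(Exception):
    """Base class for all package errors."""


class FormatError(DyskitError):
    """A file does not conform to the expected dialect (header, columns)."""


class DataError(DyskitError):
    """Well-formed input carrying invalid content (bad scores, bad timestamps)."""


class UnsynchronizableRecordingError(DataError):
    """The four sensor streams share no common time overlap."""


class ConfigurationError(DyskitError):
    """Invalid configuration value (non-stochastic matrix, bad budget, ...)."""


class SchemaError(DyskitError):
    """Feature-table column mismatch between fitted artefacts and new data."""


class ScreeningError(DyskitError):
    """Feature-class screening cannot run (e.g. single-label data)."""
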