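"""Exception hierarchy shared across the pipeline."""


class OsaprogError(Exception):
    """Base class for all package errors."""


class FormatError(OsaprogError):
    """A file does not conform to the expected on-disk format."""


class AlignmentError(OsaprogError):
    """Annotations and signal disagree about the record duration."""


class InsufficientDataError(OsaprogError):
    """Not enough samples/beats/minutes to run the requested operation."""


class ConfigurationError(OsaprogError):
    """A configuration value is out of its admissible range."""
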