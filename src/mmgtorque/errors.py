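"""Exception hierarchy.

All package errors derive from :class:`MMGTorqueError` so callers can catch
one base class at pipeline boundaries while tests can assert on the precise
failure mode.
"""


class MMGTorqueError(Exception):
    """Base class for all mmgtorque errors."""


class FormatError(MMGTorqueError):
    """A file does not conform to the expected on-disk format."""


class ChannelParseError(FormatError):
    """A channel-file row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MetadataError(MMGTorqueError):
    """Declared metadata (e.g. sampling rate) is inconsistent with the data."""


class ParameterError(MMGTorqueError):
    """An argument is outside its valid domain."""


class NormalizationError(MMGTorqueError):
    """A series cannot be normalized (all-zero or negative values)."""


class TrainingError(MMGTorqueError):
    """Network training failed (non-finite loss or invalid configuration)."""


class ModelLoadError(MMGTorqueError):
    """A serialized model file is missing, truncated or incompatible."""


class EvaluationError(MMGTorqueError):
    """An evaluation statistic is undefined for the given inputs."""


class InputError(MMGTorqueError):
    """Inconsistent multi-session input to an aggregate analysis."""
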