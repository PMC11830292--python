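"""Exception hierarchy for the pcgnet pipeline.

Batch runs over clinical recordings must be able to skip individual bad
files (corrupt RIFF chunks, empty payloads) without aborting, so format
and empty-signal failures get their own catchable types.
"""


class PcgnetError(Exception):
    """Base class for all pcgnet errors."""


class ValidationError(PcgnetError, ValueError):
    """Invalid argument or configuration value."""


class FormatError(PcgnetError):
    """Unreadable, truncated, or non-WAV input file."""


class EmptySignalError(FormatError):
    """A WAV file whose audio payload holds zero samples."""


class TrainingError(PcgnetError):
    """Numeric failure during optimisation (e.g. divergence to NaN)."""
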