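"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`HrAgreeError`
so callers can catch the package's failures without masking genuine bugs.
"""


class HrAgreeError(Exception):
    """Base class for all errors raised by hragree."""


class StreamFormatError(HrAgreeError):
    """CSV file does not match the expected dialect (header, column types)."""


class StreamOrderingError(HrAgreeError):
    """Timestamps within a stream are duplicated or not strictly increasing."""


class HeartRateRangeError(HrAgreeError):
    """A heart-rate value lies outside the plausible [0, 250] bpm range."""


class RegistryError(HrAgreeError):
    """Participant bookkeeping failure: unknown or duplicate participant id."""


class AgeRangeError(HrAgreeError):
    """Participant age outside the supported 18-120 year range."""


class PairingError(HrAgreeError):
    """Two streams cannot be paired (e.g. different participants)."""


class InsufficientDataError(HrAgreeError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(HrAgreeError):
    """Data carry no variance (or are otherwise degenerate) for the statistic."""


class UndefinedInputError(HrAgreeError):
    """An input outside the operation's domain, e.g. zone of a zero heart rate."""


class ConfigError(HrAgreeError):
    """Pipeline configuration invalid or inconsistent with the data on disk."""
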