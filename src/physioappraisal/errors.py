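"""Exception types shared across the pipeline stages."""


class PhysioAppraisalError(Exception):
    """Base class for all package errors."""


class ConfigError(PhysioAppraisalError):
    """Invalid configuration value; the message names the offending field."""


class SegmentError(PhysioAppraisalError):
    """Segment bounds outside the recording, or malformed segment index."""


class MissingChannelError(PhysioAppraisalError):
    """A recording lacks one of the required physiological channels."""


class ParseError(PhysioAppraisalError):
    """Malformed on-disk input; the message names file and line."""


class EmptyTaskError(PhysioAppraisalError):
    """A regression task is empty after missing-rating exclusion."""
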