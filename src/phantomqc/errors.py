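"""Exception hierarchy.

Every error raised by this package derives from :class:`PhantomQCError`,
so callers (and the CLI) can distinguish validation problems (exit 1)
from I/O problems (exit 2).
"""


class PhantomQCError(Exception):
    """Base class for all package errors."""


class ValidationError(PhantomQCError):
    """Input violates a documented invariant (bad values, bad names)."""


class FileFormatError(PhantomQCError):
    """File exists but is not in the expected format."""


class InsufficientDataError(ValidationError):
    """Too few time points to compute the requested quantity."""


class InsufficientHistoryError(ValidationError):
    """Too few longitudinal observations for control limits."""


class DetectionError(ValidationError):
    """No phantom-like object found in the volume."""


class ROIError(ValidationError):
    """A region of interest is empty or ill-defined."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the estimator (e.g. zero background noise)."""


class ConfigurationError(ValidationError):
    """Invalid configuration (duplicate anomaly index, unknown key, ...)."""


class StoreLookupError(PhantomQCError):
    """Requested scanner/session is absent from the metric store."""
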