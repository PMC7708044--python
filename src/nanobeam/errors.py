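"""Exception hierarchy.

All user-facing validation failures raise :class:`ValidationError` (mapped to
exit code 2 by the CLI); numerical failures raise :class:`NumericalError`
(exit code 3).
"""


class NanobeamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NanobeamError, ValueError):
    """Invalid input: bad design parameters, out-of-range values, overlaps."""


class NumericalError(NanobeamError, RuntimeError):
    """Numerical failure during a solve or fit."""


class SingularSystemError(NumericalError):
    """The spring network has no connected load path between the end plates."""


class CalibrationRangeError(ValidationError):
    """A calibration target lies outside the attainable stiffness range."""


class InsufficientDataError(ValidationError):
    """A trajectory does not contain enough usable plateaus for a fit."""
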