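"""Exception hierarchy shared across the package.

Error classes map onto CLI exit codes: configuration problems exit 2,
I/O problems exit 3, and numeric failures (NaN losses, degenerate
statistics) exit 4.
"""


class MsreconError(Exception):
    """Base class for all package errors."""


class DimensionError(MsreconError, ValueError):
    """Array shapes or sizes violate an operation's contract."""


class ConfigurationError(MsreconError, ValueError):
    """Inconsistent or incomplete configuration."""


class NumericError(MsreconError, ArithmeticError):
    """Non-finite values or degenerate statistics encountered."""


class DegenerateRoiError(NumericError):
    """An ROI is too small or has zero variance, so SNR/CNR is undefined."""
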