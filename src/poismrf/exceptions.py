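"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``NumericError`` to exit code 3.
"""


class PoismrfError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PoismrfError, ValueError):
    """Invalid user-supplied configuration (bad phantom geometry, bad rates, ...)."""


class ImageFormatError(ConfigurationError):
    """A file could not be interpreted as a 2-D image."""


class NumericError(PoismrfError, RuntimeError):
    """A numerical operation failed (singular system, impossible data, ...)."""


class SingularSystemError(NumericError):
    """Normal equations are singular or too ill-conditioned to solve."""
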