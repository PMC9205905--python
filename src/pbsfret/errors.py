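"""Exception hierarchy.

``PbsError`` is the base; the CLI maps ``ConfigError`` to exit code 1 and
``DataError``/``FormatError`` to exit code 2.
"""


class PbsError(Exception):
    """Base class for all package errors."""


class FormatError(PbsError):
    """A structure file could not be parsed."""


class NoAtomsError(FormatError):
    """A structure file parsed but contains no atoms."""


class ConfigError(PbsError):
    """An assembly-map or run configuration is invalid."""


class DataError(PbsError):
    """Input data violates a precondition (degenerate geometry, missing dipole...)."""
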