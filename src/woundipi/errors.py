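"""Exception taxonomy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`woundipi.cli`), so
callers can distinguish malformed files from degenerate-but-well-formed
inputs without parsing messages.
"""


class WoundIPIError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(WoundIPIError):
    """A file could not be parsed under its declared dialect."""

    exit_code = 3


class ValidationError(WoundIPIError):
    """Parsed data violates a type invariant (non-finite values, bad mask values...)."""

    exit_code = 4


class EmptyMaskError(ValidationError):
    """An operation that requires a non-empty mask received an all-zero one."""

    exit_code = 4


class NoCandidateError(WoundIPIError):
    """Wound segmentation produced no candidate regions."""

    exit_code = 5


class DegenerateInputError(WoundIPIError):
    """Input is well-formed but the quantity is undefined on it (e.g. constant image)."""

    exit_code = 6


class UsageError(WoundIPIError):
    """Caller error: mismatched modalities, absent labels, empty seeds..."""

    exit_code = 2


class SpecError(WoundIPIError):
    """A phantom specification is geometrically or physically inconsistent."""

    exit_code = 7
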