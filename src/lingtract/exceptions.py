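"""Exception hierarchy shared across the package."""


class LingtractError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LingtractError):
    """An on-disk file is malformed or has unsupported geometry."""


class ValidationError(LingtractError, ValueError):
    """Tabular input violates a declared constraint."""


class InputError(LingtractError, ValueError):
    """In-memory inputs are inconsistent (grid mismatch, empty seed, ...)."""


class AnatomyError(LingtractError):
    """The anatomy cannot support the requested operation."""


class ParameterError(LingtractError, ValueError):
    """A numeric parameter is outside its valid domain."""
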