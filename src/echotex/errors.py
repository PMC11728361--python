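"""Exception hierarchy used across the pipeline."""


class EchotexError(Exception):
    """Base class for all package errors."""


class InputError(EchotexError):
    """An input file is missing or unreadable."""


class FormatError(EchotexError):
    """A table or file is structurally malformed (e.g. missing column)."""


class ValidationError(EchotexError):
    """Values violate a documented precondition or invariant."""


class GenerationError(EchotexError):
    """A synthetic image target is infeasible within the 8-bit range."""


class FitError(EchotexError):
    """Nonlinear fit failed to converge from every start."""
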