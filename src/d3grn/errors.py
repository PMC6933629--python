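"""Exception types shared across the package."""


class D3GRNError(Exception):
    """Base class for all package-specific errors."""


class FormatError(D3GRNError, ValueError):
    """A file or in-memory structure violates the expected dialect."""


class ResolutionError(D3GRNError, KeyError):
    """A gene name could not be resolved against the expression matrix."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return str(self.args[0]) if self.args else ""


class ValidationError(D3GRNError, ValueError):
    """Numerical input violates a precondition (shape, finiteness, range)."""


class ConfigurationError(D3GRNError, ValueError):
    """A parameter value is outside its admissible range."""
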