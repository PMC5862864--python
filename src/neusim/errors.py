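"""Exception types used across the package."""


class NeusimError(Exception):
    """Base class for all package errors."""


class DSLSyntaxError(NeusimError, ValueError):
    """Malformed statement or expression in the equation dialect.

    Carries best-effort line/column information relative to the text that was
    being parsed.
    """

    def __init__(self, message, line=None, col=None, text=None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col
        self.text = text


class UnknownIdentifierError(DSLSyntaxError):
    """An expression references a name that is not declared anywhere."""


class ModelError(NeusimError, ValueError):
    """Inconsistent specification or failure while flattening a model."""


class SolverError(NeusimError, RuntimeError):
    """Numerical integration failure (e.g., non-finite state)."""
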