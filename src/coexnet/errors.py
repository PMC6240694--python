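"""Exception hierarchy.

ValidationError covers inconsistent or out-of-contract inputs (exit code 2
in the CLI); ParseError covers malformed files; ComputationError wraps
failures inside a pipeline stage (exit code 3).
"""


class CoexnetError(Exception):
    """Base class for all package errors."""


class ValidationError(CoexnetError, ValueError):
    """Input violates a declared invariant."""


class ParseError(CoexnetError, ValueError):
    """A file could not be parsed; message names the offending location."""


class ComputationError(CoexnetError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
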