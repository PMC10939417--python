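"""Exception hierarchy.

``ValidationError`` covers malformed inputs and violated invariants (CLI exit
code 2); every other failure surfaces as ``PoolmethError`` or a builtin (exit 3).
"""


class PoolmethError(Exception):
    """Base class for all package errors."""


class ValidationError(PoolmethError):
    """Invalid input data or parameters."""


class ParseError(ValidationError):
    """Malformed line in an input file; message names the line number."""
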