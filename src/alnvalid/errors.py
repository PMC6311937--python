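"""Exception hierarchy.

All package errors derive from :class:`AlnvalidError` so callers can catch
one base class; contract violations additionally derive from ``ValueError``.
"""


class AlnvalidError(Exception):
    """Base class for all errors raised by alnvalid."""


class FormatError(AlnvalidError, ValueError):
    """Malformed input file (ragged alignment rows, duplicate ids, empty file)."""


class AmbiguousLabelError(FormatError):
    """A sequence id is listed under two different family labels."""


class ContractError(AlnvalidError, ValueError):
    """An operation precondition or domain invariant was violated."""


class DegenerateInputError(ContractError):
    """Input is structurally valid but degenerate (e.g. all columns gap-gap)."""


class ScoringError(AlnvalidError, ValueError):
    """A residue has no substitution-matrix entry and no neutral fallback."""


class ToolError(AlnvalidError, RuntimeError):
    """An external alignment tool failed; carries the captured output."""

    def __init__(self, message: str, stdout: str = "", stderr: str = ""):
        super().__init__(message)
        self.stdout = stdout
        self.stderr = stderr


class IntegrityError(AlnvalidError, RuntimeError):
    """External tool output does not cover the input sequences."""
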