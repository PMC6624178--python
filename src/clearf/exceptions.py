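"""Error hierarchy.

Every error raised by this package carries a short machine-readable ``code``
(e.g. ``"missing-data"``, ``"shape-mismatch"``) so that the CLI can map any
failure to a one-line diagnostic and a nonzero exit status.
"""

from __future__ import annotations


class ClearFError(Exception):
    """Base class for all package errors.

    Parameters
    ----------
    code : str
        Short stable identifier of the error condition.
    message : str
        Human-readable explanation.
    """

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


class ValidationError(ClearFError):
    """A dataset or parameter violated an invariant."""


class IOFormatError(ClearFError):
    """A file could not be parsed under the declared dialect."""
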