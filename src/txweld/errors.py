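"""Exception hierarchy.

``ParseError`` — malformed input file (carries a line number when known).
``IntegrityError`` — inputs are individually well-formed but cross-reference
unknown ids or violate a structural contract.
"""

from __future__ import annotations


class TxweldError(Exception):
    """Base class for all package errors."""


class ParseError(TxweldError):
    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line is not None:
            loc += f"{line}:"
        super().__init__(f"{loc} {message}" if loc else message)
        self.path = path
        self.line = line


class IntegrityError(TxweldError):
    """Cross-file inconsistency (unknown transcript/contig id, bad segment)."""
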