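"""Exception hierarchy shared across the package."""


class CollabflowError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CollabflowError):
    """A corpus file line could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class SchemaError(CollabflowError):
    """A record or file violates the documented schema (missing field,
    wrong type, unrecognized label)."""


class IntegrityError(CollabflowError):
    """Input is well-formed but internally inconsistent (duplicate ids,
    conflicting sector labels, self-references)."""


class UnknownPaperError(CollabflowError, KeyError):
    """An operation was handed a paper id absent from the corpus."""


class UndefinedIndexError(CollabflowError, ValueError):
    """A network index is mathematically undefined for this input
    (e.g. an edgeless graph has no industrial participation fraction)."""
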