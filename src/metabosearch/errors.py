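"""Exception hierarchy.

Everything raised on bad data derives from :class:`MetaboSearchError`, so the
CLI can map "data problem" to one exit code while genuine bugs still surface
as ordinary tracebacks.
"""


class MetaboSearchError(Exception):
    """Base class for all data/usage errors raised by this package."""


class FormulaParseError(MetaboSearchError):
    """A molecular-formula string does not follow the element-count grammar."""


class ElementError(MetaboSearchError):
    """An element symbol is absent from the element mass table."""


class HypothesisError(MetaboSearchError):
    """An ion hypothesis yields a nonsensical (non-positive) neutral mass."""


class SchemaError(MetaboSearchError):
    """A tabular input is missing mandatory columns."""


class DialectError(MetaboSearchError):
    """A flat-file line does not conform to the expected column layout."""


class EmptyInputError(MetaboSearchError):
    """An input table or query batch contains no usable rows."""


class CapabilityError(MetaboSearchError):
    """A database cannot serve the requested search (e.g. no masses stored)."""
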