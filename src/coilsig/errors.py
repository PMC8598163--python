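"""Exception hierarchy.

All coilsig errors derive from :class:`CoilsigError`; most are also
``ValueError`` subclasses so that callers who do not care about the finer
distinction can catch the builtin type.
"""


class CoilsigError(Exception):
    """Base class for all coilsig exceptions."""


class FormatError(CoilsigError, ValueError):
    """A file or string does not conform to the expected format."""


class RangeError(CoilsigError, ValueError):
    """A numeric value lies outside its permitted range."""


class ConsistencyError(CoilsigError, ValueError):
    """Two inputs that must agree (e.g. an alignment row and its score
    profile) do not."""


class UndefinedResultError(CoilsigError, ValueError):
    """The requested quantity is mathematically undefined for the given
    input (e.g. a mean over zero retained columns)."""


class SaturationError(CoilsigError, ValueError):
    """A pairwise difference proportion is saturated (p >= 1), so the
    distance correction diverges."""
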