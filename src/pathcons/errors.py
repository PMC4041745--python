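"""Exception hierarchy shared by all pipeline stages."""


class PathconsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PathconsError):
    """A file does not conform to its declared format (missing columns,
    too few fields, unparseable required values)."""


class ValidationError(PathconsError):
    """Well-formed input violates a semantic invariant (p outside [0,1],
    empty interval, duplicate identifier, inconsistent configuration)."""
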