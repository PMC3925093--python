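"""Package exceptions.

All dcgrn errors derive from :class:`DcgrnError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class DcgrnError(Exception):
    """Base class for all dcgrn errors."""


class InvalidInputError(DcgrnError, ValueError):
    """An argument violates an operation's contract (shape, range, tag)."""


class DataFormatError(DcgrnError, ValueError):
    """A file on disk does not conform to the expected text format."""
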