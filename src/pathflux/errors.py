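"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PathfluxError` so a
CLI wrapper can catch one type and exit nonzero with the message.
"""


class PathfluxError(Exception):
    """Base class for all pathflux errors."""


class NetworkParseError(PathfluxError):
    """A network file could not be parsed; the message names the line."""


class ValidationError(PathfluxError):
    """A data-model invariant is violated (weights, duplicates, ranges)."""


class ConfigurationError(PathfluxError):
    """An impossible or incomplete configuration (e.g. no exit node)."""


class LookupMismatchError(PathfluxError):
    """An id is missing where one is required (compound, target, join key)."""


class ZeroVarianceError(PathfluxError):
    """Correlation requested on a constant vector."""
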