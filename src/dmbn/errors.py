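"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`DmbnError` so the command line
layer can report them as clean messages (exit status 2) instead of tracebacks.
"""


class DmbnError(Exception):
    """Base class for all dmbn errors."""


class FormatError(DmbnError):
    """A file or table violates the expected format or value alphabet."""


class DimensionError(DmbnError):
    """Mismatched shapes between objects that must align."""


class StructureError(DmbnError):
    """A graph violates a structural requirement (e.g. acyclicity)."""


class ConsistencyError(DmbnError):
    """Mutually contradictory constraints (e.g. background vs. v-structure)."""
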