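"""Exception hierarchy shared across the package."""


class CyclemurError(Exception):
    """Base class for all package errors."""


class ConfigError(CyclemurError):
    """Invalid configuration value or combination."""


class DomainError(CyclemurError):
    """Input outside an operation's mathematical domain."""


class AlignmentError(CyclemurError):
    """Species identifiers do not line up across inputs."""


class SchemaError(CyclemurError):
    """Malformed input file; carries offending row/line context."""
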