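"""Exception taxonomy shared across the package.

All errors derive from :class:`Rnam5cError` so callers (and the CLI) can
distinguish data/validation problems (exit code 1) from usage errors.
"""


class Rnam5cError(Exception):
    """Base class for all package errors."""


class ValidationError(Rnam5cError):
    """Invalid argument values or malformed inputs."""


class CoverageError(ValidationError):
    """Zero total read coverage where a methylation level is required."""


class WindowError(Rnam5cError):
    """A sequence window could not be extracted for a site."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside {A, C, G, U, N}."""


class SchemaError(Rnam5cError):
    """Feature names/order do not match what a model expects."""


class DegenerateSplitError(Rnam5cError):
    """A training split ended up with fewer than two classes."""


class CapacityError(Rnam5cError):
    """A simulation request exceeds what the sequences can accommodate."""
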