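"""Exception hierarchy.

All errors raised by the package derive from :class:`CloneshareError` so that
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class CloneshareError(Exception):
    """Base class for all package errors."""


class FormatError(CloneshareError):
    """A file does not conform to its declared dialect or format."""


class IntegrityError(CloneshareError):
    """Cross-table consistency violated (e.g. a barcode mapped to two subjects)."""


class ValidationError(CloneshareError):
    """Invalid argument values or records failing their invariants."""
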