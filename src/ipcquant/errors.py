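"""Exception hierarchy shared across the package.

``ValidationError`` flags inputs that parse but violate a domain invariant
(non-monotone time, impossible counts, rejected ROIs).  ``FormatError`` flags
files that cannot be interpreted at all (missing columns, empty data).  The
command-line layer maps these onto exit code 1 and everything else onto 2.
"""


class IpcQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IpcQuantError, ValueError):
    """A file or table does not have the expected structure."""


class ValidationError(IpcQuantError, ValueError):
    """Structurally valid data violates a domain invariant."""


class DegenerateTraceError(ValidationError):
    """A fluorescence trace is unusable (e.g. all-zero after correction)."""
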