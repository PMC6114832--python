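"""Exception hierarchy.

``PseUIError`` is the common base so callers can catch everything from this
package with one clause. ``FormatError`` covers structurally broken input
files; ``ValidationError`` covers well-formed input that violates a domain
invariant (wrong alphabet, wrong segment length, center not U, ...).
"""


class PseUIError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PseUIError):
    """Input file is not in the expected format."""


class ValidationError(PseUIError):
    """Input violates a domain invariant."""


class BundleLoadError(PseUIError):
    """A persisted model bundle is corrupt or version-incompatible."""
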