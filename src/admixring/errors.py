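"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`AdmixRingError` so the
command-line layer can turn it into a one-line diagnostic instead of a
traceback.
"""


class AdmixRingError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AdmixRingError):
    """Malformed input file (ragged rows, too few columns, bad hex color)."""


class ValidationError(AdmixRingError):
    """Structurally valid input that violates a data invariant."""


class UnknownLabelError(AdmixRingError):
    """A population label was requested that does not exist in the dataset."""
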