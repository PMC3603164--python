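"""Exception types shared across the pipeline."""


class EntrosegError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(EntrosegError):
    """Raised when an image file has an extension we do not handle."""


class DegenerateImageError(EntrosegError):
    """Raised when an image (or region) carries no usable signal.

    Examples: a single-valued channel offered for threshold selection, or a
    region whose probability mass is zero so its entropy is undefined.
    """


class CapacityError(EntrosegError):
    """Raised when the synthetic generator cannot place the requested nuclei."""
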