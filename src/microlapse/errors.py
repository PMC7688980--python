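"""Exception hierarchy shared by all microlapse modules."""


class MicrolapseError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatch(MicrolapseError):
    """Inputs that must share a shape do not."""


class ShapeError(MicrolapseError):
    """A single input has an unusable shape (too small, non-square, odd Bayer dims)."""


class ReadError(MicrolapseError):
    """A file exists but could not be decoded; the message names the file."""


class DegenerateInput(MicrolapseError):
    """An input carries no usable signal (e.g. a constant image for correlation)."""


class EmptyInput(MicrolapseError):
    """An operation received an empty collection."""


class AllExcluded(MicrolapseError):
    """Quality control rejected every frame."""


class ConfigError(MicrolapseError):
    """A configuration field is inconsistent; the message names the field."""
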