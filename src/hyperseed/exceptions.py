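"""Exception hierarchy shared across the package."""


class HyperseedError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HyperseedError, ValueError):
    """An argument is outside the domain an operation is defined on."""


class DegenerateInputError(DomainError):
    """Input is structurally valid but degenerate (constant spectrum, flat image)."""


class FormatError(HyperseedError, IOError):
    """A file exists but its content contradicts its declared format."""


class CalibrationError(DomainError):
    """White and dark references coincide where a reflectance division is required."""
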