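"""Exception hierarchy.

All errors derive from :class:`CishquantError` so callers can catch the whole
family; most also derive from :class:`ValueError` because they signal invalid
inputs rather than internal failures.
"""


class CishquantError(Exception):
    """Base class for all package errors."""


class ParameterError(CishquantError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(CishquantError, ValueError):
    """An input file violates the expected tabular/image format."""


class RangeError(CishquantError, ValueError):
    """A wavelength query falls outside the supported spectral range."""


class ShapeError(CishquantError, ValueError):
    """Array shapes are inconsistent."""


class DegeneracyError(CishquantError, ValueError):
    """A computation is ill-posed (collinear spectra, constant data...)."""


class InsufficientDataError(CishquantError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigurationError(CishquantError, ValueError):
    """A pipeline configuration value is missing or inconsistent."""


class EmptyInputError(CishquantError, ValueError):
    """An operation received an empty mask or region."""
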