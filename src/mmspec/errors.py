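"""Exception hierarchy for the mmspec toolkit.

All package-specific failures derive from :class:`MmspecError` so callers
(including the CLI) can catch one base class and exit with a nonzero status.
"""


class MmspecError(Exception):
    """Base class for all mmspec errors."""


class UnitError(MmspecError, ValueError):
    """Axis kinds or units of two spectra are incompatible."""


class AxisRangeError(MmspecError, ValueError):
    """A requested wavelength/wavenumber lies outside the spectral axis."""


class BoundsError(MmspecError, IndexError):
    """A detector region of interest lies outside the CCD frame."""


class ConfigError(MmspecError, ValueError):
    """Invalid preprocessing or simulation configuration."""


class CalibrationError(MmspecError, RuntimeError):
    """Wavenumber calibration could not be established."""


class DegenerateInputError(MmspecError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-zero)."""


class InsufficientReplicatesError(MmspecError, ValueError):
    """Too few replicate spectra for a statistic."""


class NoTroughError(MmspecError, RuntimeError):
    """No interior reflectance minimum found in the search band."""


class NormalizationError(MmspecError, ValueError):
    """A required normalization reference (e.g. thickness 0) is missing."""


class EmptyResultError(MmspecError, ValueError):
    """An operation produced an empty spectrum (e.g. crop with no overlap)."""


class SpectrumIOError(MmspecError, ValueError):
    """A spectrum or frame file is malformed."""
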