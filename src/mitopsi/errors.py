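"""Exception hierarchy for mitopsi.

All errors derive from :class:`MitopsiError` so callers can catch the
package's failures with a single except clause; most also derive from the
matching builtin (ValueError etc.) so generic handling keeps working.
"""


class MitopsiError(Exception):
    """Base class for all mitopsi errors."""


class MaskedWavelengthError(MitopsiError, ValueError):
    """Dark-corrected intensity is non-positive at one or more wavelengths.

    Carries the offending wavelengths so saturated or blocked channels can
    be traced back to the instrument.
    """

    def __init__(self, message, wavelengths_nm=None):
        super().__init__(message)
        self.wavelengths_nm = wavelengths_nm


class GridAlignmentError(MitopsiError, ValueError):
    """Two spectra do not share a wavelength grid; resample first."""


class GridDomainError(MitopsiError, ValueError):
    """Requested wavelengths fall outside the source grid (extrapolation)."""


class WindowSizeError(MitopsiError, ValueError):
    """A rolling/averaging window does not fit the series."""


class RankDeficientError(MitopsiError, ValueError):
    """The unmixing design matrix is (numerically) rank deficient."""

    def __init__(self, message, condition_number=None):
        super().__init__(message)
        self.condition_number = condition_number


class CalibrationError(MitopsiError, ValueError):
    """Electrode or sigmoid calibration could not be established."""


class DegenerateFitError(CalibrationError):
    """A fit collapsed onto a degenerate solution (e.g. bottom == top)."""


class ConfigurationError(MitopsiError, ValueError):
    """Mutually inconsistent component configuration (hard stop)."""


class DomainError(MitopsiError, ValueError):
    """An input lies outside the mathematical domain of an operation."""
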