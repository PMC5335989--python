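"""Exception hierarchy for cherryripe.

All package errors derive from :class:`CherryRipeError` so callers can catch
one base class; each also derives from the matching builtin so generic
handlers keep working.
"""


class CherryRipeError(Exception):
    """Base class for all cherryripe errors."""


class ValidationError(CherryRipeError, ValueError):
    """Invalid input data or parameters."""


class BandRangeError(CherryRipeError, ValueError):
    """A requested extraction band lies outside the measured spectral range."""


class DegenerateSeriesError(CherryRipeError, ValueError):
    """A time series is constant (or otherwise unfittable in principle)."""


class FitError(CherryRipeError, RuntimeError):
    """Curve fitting failed to converge for every admissible family."""


class CalibrationError(CherryRipeError, RuntimeError):
    """Pre-t0 rate calibration produced a non-positive (non-ripening) slope."""


class ConfigurationError(CherryRipeError, ValueError):
    """Missing or inconsistent configuration (criteria, rates, CLI options)."""


class NoDataError(CherryRipeError, ValueError):
    """A query matched no non-missing values."""


class FixtureIntegrityError(CherryRipeError, RuntimeError):
    """A packaged fixture file does not match its manifest checksum."""
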