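"""Exception hierarchy shared across the package.

Everything derives from :class:`TriaxError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
stage that raised them (file format, geometry, sensor calibration, ...).
"""


class TriaxError(Exception):
    """Base class for all triaxmeg errors."""


class FormatError(TriaxError):
    """An on-disk file does not conform to the documented layout."""


class UnitError(FormatError):
    """A required unit attribute is absent or unrecognised."""


class ValidationError(TriaxError):
    """An in-memory object violates its invariants."""


class GeometryError(TriaxError):
    """Degenerate or inconsistent geometric input."""


class ConfigurationError(TriaxError):
    """A parameter combination that cannot be simulated/analysed."""


class CalibrationError(TriaxError):
    """Sensor calibration failed (e.g. singular crosstalk response)."""


class SignalError(TriaxError):
    """A signal lacks the structure an operation requires."""


class FitError(TriaxError):
    """An inverse fit cannot be performed on the given data."""


class DomainError(TriaxError):
    """A field evaluation point lies outside the model's domain."""
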