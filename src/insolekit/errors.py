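"""Exception hierarchy for insolekit.

All errors derive from :class:`InsoleKitError` so callers can catch the
package's failures with a single except clause; most also derive from the
matching builtin (``ValueError``) for drop-in ergonomics.
"""


class InsoleKitError(Exception):
    """Base class for all insolekit errors."""


class GeometryError(InsoleKitError, ValueError):
    """Invalid sensor geometry (non-positive area, zero effective gap...)."""


class PressureRangeError(InsoleKitError, ValueError):
    """Pressure outside the sensor's working range or otherwise out of domain."""


class FormatError(InsoleKitError, ValueError):
    """Malformed file or non-uniformly sampled trace."""


class InsufficientDataError(InsoleKitError, ValueError):
    """Not enough samples/cycles/levels for the requested statistic."""


class FitError(InsoleKitError, ValueError):
    """Degenerate regression input."""


class UndefinedHysteresisError(InsoleKitError, ValueError):
    """Loading-curve area is zero; degree of hysteresis undefined."""


class NoEdgeError(InsoleKitError, ValueError):
    """No qualifying rising/falling edge found in the trace."""


class CalibrationError(InsoleKitError, ValueError):
    """Missing or inconsistent calibration constants."""


class ConfigurationError(InsoleKitError, ValueError):
    """Inconsistent configuration (wrong sensor count, bad protocol...)."""
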