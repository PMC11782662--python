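"""Exception hierarchy shared across the package."""


class CondensaxError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CondensaxError, ValueError):
    """A numeric parameter is outside its admissible range."""


class InvalidGeometryError(CondensaxError, ValueError):
    """A spherocylinder or chain violates its geometric invariants."""


class EmptyModelError(CondensaxError, ValueError):
    """A scattering model contains no particles."""


class GridMismatchError(CondensaxError, ValueError):
    """Model and experiment do not share a q grid inside the fit window."""


class ResolutionError(CondensaxError, ValueError):
    """Requested fit window extends below the window-function resolution 2pi/sigma_w."""


class DegenerateWindowError(CondensaxError, ValueError):
    """Fewer than the minimum number of data points fall inside the fit window."""


class OvercrowdedPlacementError(CondensaxError, RuntimeError):
    """Clash-free placement failed within the retry budget."""


class ParseError(CondensaxError, ValueError):
    """A text input file could not be parsed."""


class ConfigError(CondensaxError, ValueError):
    """A run configuration is invalid or contains unknown keys."""
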