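"""Exception hierarchy shared across the package."""


class SpotdiffError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SpotdiffError, ValueError):
    """Malformed or out-of-contract input data."""


class InvalidParameterError(SpotdiffError, ValueError):
    """A parameter value outside its admissible range."""


class DegenerateGeometryError(SpotdiffError, ValueError):
    """Coordinates that do not define a usable grid (e.g. all coincident)."""


class TopologyMismatchError(SpotdiffError, ValueError):
    """A stencil applied to a grid of the wrong topology."""


class NumericalInstabilityError(SpotdiffError, ArithmeticError):
    """NaN/Inf appeared during time propagation; dt too large."""


class UndefinedEntropyError(SpotdiffError, ValueError):
    """Entropy requested for a subset with zero total mass."""
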