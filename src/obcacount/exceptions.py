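"""Exception types raised across the package."""


class ObcaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ObcaError):
    """An input file or array has an unsupported layout (e.g. RGB, multi-plane)."""


class ShapeMismatchError(ObcaError):
    """Two images or point sets that must share dimensions do not."""


class ParameterError(ObcaError):
    """A parameter violates its documented precondition."""


class DegenerateHistogramError(ObcaError):
    """The intensity histogram has fewer distinct populated bins than classes."""


class BoundsError(ObcaError):
    """A coordinate falls outside the image domain."""


class PlacementError(ObcaError):
    """The synthetic generator could not satisfy a placement constraint."""


class UndefinedStatisticError(ObcaError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
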