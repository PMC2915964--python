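"""Exception types shared across the package."""


class ShapeQTLError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(ShapeQTLError, ValueError):
    """An array has the wrong shape (non-square image, mismatched sizes...)."""


class DegenerateShapeError(ShapeQTLError, ValueError):
    """A binary image is all-foreground or all-background, so no contour
    (and hence no signed distance) exists."""


class InvalidPoseError(ShapeQTLError, ValueError):
    """A pose parameter violates its domain (e.g. non-positive scale)."""


class MapDomainError(ShapeQTLError, ValueError):
    """A genetic position lies outside the linkage map span, or a map
    distance is negative."""


class EmptyComponentError(ShapeQTLError, RuntimeError):
    """A mixture component lost essentially all posterior mass during EM."""


class ParameterError(ShapeQTLError, ValueError):
    """A simulation parameter produces an invalid shape (e.g. boundary
    outside the grid)."""
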