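"""Exception hierarchy shared across the package."""


class LumigainError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(LumigainError, ValueError):
    """A stimulus or model specification is internally inconsistent."""


class GeometryError(LumigainError, ValueError):
    """A spatial layout request cannot be satisfied (aperture > screen, ...)."""


class UndefinedContrastError(LumigainError, ValueError):
    """Contrast is undefined for the given luminance values (e.g. all zero)."""


class DivisionDegenerateError(LumigainError, ZeroDivisionError):
    """A divisive normalization would divide by zero."""


class FitDegenerateError(LumigainError, ValueError):
    """The data cannot constrain the requested fit."""


class DegenerateGeometryError(LumigainError, ValueError):
    """A point cloud is rank-deficient for the requested geometry computation."""


class DegenerateFitWarning(UserWarning):
    """A fit converged to a boundary or otherwise uninformative solution."""
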