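"""Exception hierarchy shared across the package."""


class CabbageError(Exception):
    """Base class for all package errors."""


class PointCloudParseError(CabbageError):
    """A point-cloud file could not be parsed; message names the offending location."""


class ValidationError(CabbageError, ValueError):
    """Input data violates a structural invariant (NaN coordinate, bad shape, ...)."""


class MissingAttributeError(CabbageError):
    """An operation requires an attribute (e.g. colors) the cloud does not carry."""


class DegenerateGeometryError(CabbageError):
    """Geometry too degenerate for the requested quantity (collinear, coplanar, zero extent)."""


class InsufficientPointsError(CabbageError):
    """Too few points for the requested operation."""
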