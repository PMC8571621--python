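"""Exception types raised across the package.

All inherit from :class:`LandfuseError` so callers can catch the package's
contract violations with one except clause; each subclass also derives from
the closest builtin (ValueError/KeyError/OSError) so generic handling works.
"""


class LandfuseError(Exception):
    """Base class for all landfuse contract violations."""


class HierarchyError(LandfuseError, ValueError):
    """Invalid class taxonomy: conflicting child→parent rows, empty table,
    or a code scheme the decimal-prefix rule cannot apply to."""


class LookupError_(LandfuseError, KeyError):
    """A class code absent from the hierarchy or composition it was asked of."""


class GridAlignmentError(LandfuseError, ValueError):
    """Two grids differ in shape, transform, or nodata footprint where they
    are required to coincide."""


class VerticalConsistencyError(LandfuseError, ValueError):
    """A cell whose fine-grade class does not map to the coarse-grade class
    at the same location."""


class RasterFormatError(LandfuseError, ValueError):
    """A raster file violates the categorical/continuous contract (e.g. a
    fractional value in a class-code grid)."""


class EmptyWindowError(LandfuseError, ValueError):
    """An entropy or metric operation was asked of a composition with no
    valid cells; empty windows are a flagged state upstream, an error here."""
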