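"""Exception hierarchy.

All package-specific failures derive from :class:`LobescopeError` so callers
can catch one base class at pipeline boundaries.
"""


class LobescopeError(Exception):
    """Base class for all lobescope errors."""


class TopologyMismatchError(LobescopeError):
    """Atom count or ordering differs between models/frames of one system."""


class MissingResidueError(LobescopeError):
    """An operation referenced a residue (or atom of it) absent from the model."""


class UnknownRegionError(LobescopeError):
    """Region name not present in the region scheme."""


class EmptySelectionError(LobescopeError):
    """A selection resolved to zero atoms."""


class DegenerateGeometryError(LobescopeError):
    """Geometry is ill-posed (collinear dihedral anchors, <3 fit atoms, ...)."""


class UnreachableTargetError(LobescopeError):
    """A synthetic-build target is geometrically unreachable."""


class ConfigError(LobescopeError):
    """Invalid run configuration (unknown key, missing file, bad value)."""
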