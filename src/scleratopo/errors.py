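"""Exception hierarchy.

Every failure mode raised by the pipeline derives from :class:`ScleraTopoError`
so callers (and the CLI) can distinguish pipeline errors from programming
errors, while fine-grained subclasses keep diagnostics distinct.
"""


class ScleraTopoError(Exception):
    """Base class for all errors raised by this package."""


class VolumeReadError(ScleraTopoError):
    """The volume file could not be read or parsed."""


class EmptyForegroundError(ScleraTopoError):
    """The mask contains no foreground voxels (or none for the requested label)."""


class SurfaceExtractionError(ScleraTopoError):
    """Marching cubes produced no surface (mask too small or below iso-level)."""


class UnsupportedFormatError(ScleraTopoError):
    """Requested surface file format is not supported."""


class DegenerateGeometryError(ScleraTopoError):
    """Geometry too degenerate to establish the eye frame (e.g. vertex == center)."""


class InsufficientPointsError(ScleraTopoError):
    """Too few surface points for a reliable fit or statistic."""
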