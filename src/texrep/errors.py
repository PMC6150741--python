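"""Exception hierarchy for texrep."""


class TexrepError(Exception):
    """Base class for all texrep errors."""


class GeometryError(TexrepError):
    """Phantom geometry is infeasible (e.g. tumor does not fit in the grid)."""


class ShapeMismatchError(TexrepError):
    """A volume and its mask do not live on the same voxel grid."""


class EmptyMaskError(TexrepError):
    """An operation requiring in-mask voxels received an empty mask."""


class ConfigError(TexrepError):
    """Invalid run configuration."""


class DegenerateInputError(TexrepError):
    """Input admits no valid computation (e.g. no in-mask voxel pairs)."""


class ValidationError(TexrepError):
    """Study manifest or pairing structure is invalid."""
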