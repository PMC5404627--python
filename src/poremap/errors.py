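"""Exception hierarchy shared across the package."""


class PoremapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PoremapError):
    """Malformed or inconsistent trajectory file content."""


class UnsupportedGeometryError(FormatError):
    """Non-orthorhombic (triclinic) unit cell encountered."""


class SelectionError(PoremapError):
    """A selection rule could not be applied to a residue."""


class BoundsError(PoremapError, IndexError):
    """Frame or residue index outside the valid range."""


class DimensionError(PoremapError, ValueError):
    """Mismatched array lengths or shapes."""


class DomainError(PoremapError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateInputError(PoremapError, ValueError):
    """Input too short or otherwise degenerate for the operation."""


class ParameterError(PoremapError, ValueError):
    """Invalid parameter combination."""


class AlignmentError(PoremapError, ValueError):
    """Time grids cannot be aligned without extrapolation."""
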