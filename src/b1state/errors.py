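"""Exception hierarchy shared across the package."""


class B1StateError(Exception):
    """Base class for all errors raised by b1state."""


class FormatError(B1StateError):
    """A coordinate file could not be parsed as PDB or mmCIF."""


class EmptyModelError(B1StateError):
    """A coordinate file parsed but contained no atoms."""


class CapacityError(B1StateError):
    """A model exceeds a hard format limit (e.g. >99999 atoms for PDB)."""


class RoleAssignmentError(B1StateError):
    """No chain satisfies the receptor (or required partner) criteria."""


class MissingResidueError(B1StateError):
    """A strict selector or measurement referenced a residue that is absent."""


class MissingAtomError(B1StateError):
    """A required atom (typically a C-alpha) is absent from a residue."""


class NoAnchorError(B1StateError):
    """A generic-numbering segment has no anchor for the requested receptor."""


class RangeError(B1StateError):
    """A resolved residue number falls outside the segment's author range."""


class UnmappedError(B1StateError):
    """An author residue number maps to no known segment or loop."""


class DegenerateGeometryError(B1StateError):
    """Point sets too small or collinear for a rigid superposition."""


class CorrespondenceError(B1StateError):
    """Fewer than three matched atom pairs were found for a superposition scope."""


class MotifResolutionError(B1StateError):
    """A motif member could not be resolved to a residue in the model."""


class SpecValidationError(B1StateError):
    """A comparison spec references undefined structures or is malformed."""
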