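"""Exception types raised across the package.

All are ``ValueError`` subclasses so callers that do not care about the
fine-grained taxonomy can catch a single base class.
"""


class PoselightError(ValueError):
    """Base class for all poselight errors."""


class InvalidInputError(PoselightError):
    """An input violates a mathematical precondition (e.g. non-rotation matrix)."""


class ShapeError(PoselightError):
    """Mismatched array shapes or joint counts."""


class DegenerateRDMError(PoselightError):
    """An RDM whose off-diagonal entries are constant (normalization undefined)."""


class DegenerateItemError(PoselightError):
    """An item with zero variance where variance is required (patterns, embeddings)."""


class AlignmentError(PoselightError):
    """Item identifiers of two structures cannot be aligned."""


class CollinearityError(PoselightError):
    """Target RDM linearly dependent on the control set in a partial correlation."""


class ConfigurationError(PoselightError):
    """Invalid configuration of an analysis (missing fields, bad counts)."""


class InsufficientDataError(PoselightError):
    """Not enough trials, items, or subjects for the requested computation."""


class ContractError(PoselightError):
    """Input data violate a documented data contract (e.g. repeat counts)."""


class EmptyROIError(PoselightError):
    """A voxel selection left no voxels in the ROI."""


class ParseError(PoselightError):
    """A file or record could not be parsed."""
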