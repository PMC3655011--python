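"""Exception hierarchy shared by all gtusc modules."""


class GtuscError(Exception):
    """Base class for all package-specific errors."""


class StructuralInconsistencyError(GtuscError):
    """Atom identity or atom count differs between frames of one trajectory."""


class EmptyInputError(GtuscError):
    """An input (file, frame window, cluster list ...) contained no data."""


class PoseParseError(GtuscError):
    """A pose file could not be parsed (e.g. missing per-model energy remark)."""


class UnknownChainError(GtuscError):
    """A requested chain identifier is not present in the structure."""


class GeometryError(GtuscError):
    """Degenerate geometry: too few atoms or a collinear selection."""


class MissingDescriptorError(GtuscError):
    """A fragment record lacks a property the filter specification references."""


class PoseMismatchError(GtuscError):
    """Poses with heterogeneous atom lists were given to a pairwise-RMSD step."""


class InsufficientDataError(GtuscError):
    """Fewer data points than model parameters inside the fit window."""


class GeneratorSpecError(GtuscError):
    """A synthetic-data specification is internally inconsistent or infeasible."""


class FitNotConvergedError(GtuscError):
    """A downstream step required a converged melt-curve fit but got none."""
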