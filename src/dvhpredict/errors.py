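"""Exception hierarchy shared across the package."""


class DvhPredictError(Exception):
    """Base class for all package errors."""


class GeometryError(DvhPredictError):
    """Voxel grids disagree or do not overlap spatially."""


class InvalidContourError(DvhPredictError):
    """A contour polygon violates its invariants (e.g. < 3 vertices)."""


class ModelInputError(DvhPredictError):
    """An operation received structurally empty or unusable input."""


class DegenerateTrainingError(ModelInputError):
    """Training data cannot support a bandwidth fit (too few samples or
    zero variance in one coordinate)."""


class ContractError(DvhPredictError):
    """An input violated a documented invariant (e.g. unnormalized density)."""


class RangeError(DvhPredictError):
    """A requested quantity lies outside the representable axis."""


class PairingError(DvhPredictError):
    """Predicted and achieved result sets cannot be paired plan-by-plan."""


class DegenerateFitError(DvhPredictError):
    """A regression target has zero variance; the fit is undefined."""


class MatchingError(DvhPredictError):
    """Structure-name matching failed (no target, or multiple targets)."""


class FormatError(DvhPredictError):
    """A file does not conform to the expected on-disk format."""


class VersionError(FormatError):
    """A file carries an unsupported schema version."""


class PhantomSpecError(DvhPredictError):
    """A synthetic-cohort specification is unusable (e.g. target rasterizes
    to zero voxels)."""
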