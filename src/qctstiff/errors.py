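"""Exception hierarchy for the qctstiff pipeline.

Every stage signals its failure mode with a dedicated subclass so that the
cohort driver can log and continue past a single bad specimen.
"""


class QCTStiffError(Exception):
    """Base class for all qctstiff errors."""


class GeometryError(QCTStiffError):
    """Synthetic geometry does not fit the requested grid."""


class ConfigError(QCTStiffError):
    """Invalid or incomplete configuration."""


class ROIError(QCTStiffError):
    """Tissue region of interest is empty or incongruent with the image."""


class CorticalReferenceError(QCTStiffError):
    """No bone voxel falls inside the cortical HU window."""


class DegenerateFitError(QCTStiffError):
    """Calibration points do not determine a line (e.g. identical HU)."""


class SegmentationError(QCTStiffError):
    """Bone segmentation produced an empty mask."""


class VOIError(QCTStiffError):
    """Volume-of-interest is empty after intersection."""


class MeshingError(QCTStiffError):
    """Surface or volume meshing failed (non-watertight, disconnected...)."""


class MappingError(QCTStiffError):
    """Material mapping sampled outside the density image."""


class BCError(QCTStiffError):
    """Boundary node sets are empty or the system is singular."""


class ConvergenceError(QCTStiffError):
    """Linear solve residual above tolerance."""


class IncompleteCohortError(QCTStiffError):
    """Cohort tables are missing (specimen, method) cells."""


class AgreementError(QCTStiffError):
    """Agreement statistic undefined (e.g. zero reference mean)."""
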