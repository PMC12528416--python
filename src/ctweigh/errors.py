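"""Exception and warning types shared across the pipeline."""


class CTWeighError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CTWeighError):
    """Invalid user input: missing files, malformed arguments, contract violations."""


class MetadataError(CTWeighError):
    """A required DICOM/NIfTI metadata element is absent or unusable."""


class AmbiguousSeriesError(CTWeighError):
    """A directory mixes DICOM files from more than one series."""


class SpecError(CTWeighError):
    """A phantom specification violates its invariants."""


class MaskError(CTWeighError):
    """Tissue masks violate disjointness or alignment invariants."""


class DomainError(CTWeighError):
    """A scaling factor or corrected scaling factor left its valid domain."""


class SearchError(CTWeighError):
    """Parameter calibration found no feasible candidate."""


class CTWeighWarning(UserWarning):
    """Base class for warnings emitted by this package."""


class GeometryWarning(CTWeighWarning):
    """Suspicious acquisition geometry (non-uniform gaps, thickness > spacing...)."""


class HURangeWarning(CTWeighWarning):
    """Voxel values outside the plausible CT range after rescaling."""


class TableRemovalWarning(CTWeighWarning):
    """Table removal fell back or declined on part of the volume."""
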