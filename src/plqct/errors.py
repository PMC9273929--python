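"""Exception hierarchy with pipeline stage tags.

Every error raised inside the measurement pipeline carries a ``stage``
attribute so that batch drivers (CLI, evaluation scripts) can report which
processing step failed for which volume.
"""


class PLQCTError(Exception):
    """Base class for all package errors."""

    stage: str = "general"

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        if stage is not None:
            self.stage = stage


class InputError(PLQCTError):
    stage = "io"


class AmbiguousInputError(InputError):
    """More than one (or zero) usable DICOM series found."""


class WrongModalityError(InputError):
    """Input is not an axial CT acquisition."""


class IrregularGeometryError(InputError):
    """Slice spacing varies beyond tolerance, or volume is oblique."""


class CohortSchemaError(InputError):
    """Cohort CSV has unknown columns or unparseable values."""


class NoSpineFoundError(PLQCTError):
    stage = "localization"


class LevelNotInFOVError(PLQCTError):
    """Requested vertebral level not covered by the scan."""

    stage = "localization"


class DegenerateROIError(PLQCTError):
    """Trabecular ROI eroded below the minimum voxel count."""

    stage = "roi"


class TissueROINotFoundError(PLQCTError):
    """Fat or muscle candidate region below minimum area."""

    stage = "roi"


class EmptyROIError(PLQCTError):
    stage = "roi"


class DegenerateTissueContrastError(PLQCTError):
    """|HU_muscle - HU_fat| too small for a reliable internal calibration."""

    stage = "calibration"


class DegenerateReferenceError(PLQCTError):
    """Reference labels contain a single class; ROC undefined."""

    stage = "evaluation"


class ConfigError(PLQCTError):
    stage = "config"
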