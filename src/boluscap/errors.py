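"""Exception hierarchy for the bolus-cap pipeline.

Every stage raises a subclass of :class:`BolusCapError`, so the CLI can abort
with a nonzero status that names the failing stage.
"""


class BolusCapError(Exception):
    """Base class for all pipeline errors."""


class GridError(BolusCapError):
    """Invalid grid geometry or mismatched grids."""


class SeriesReadError(BolusCapError):
    """A DICOM CT series could not be assembled into a coherent volume."""


class SegmentationError(BolusCapError):
    """Body segmentation failed (empty threshold, suspect threshold...)."""


class ShellError(BolusCapError):
    """Bolus shell construction failed."""


class MeshError(BolusCapError):
    """Mesh extraction, smoothing, or validation failed."""


class StlFormatError(BolusCapError):
    """A binary STL file is malformed."""


class QaError(BolusCapError):
    """Conformality / thickness QA could not be computed."""


class CalibrationError(BolusCapError):
    """Invalid HU-to-density calibration curve or query."""


class DosimetryError(BolusCapError):
    """Invalid TLD dose-comparison input."""
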