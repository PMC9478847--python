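"""Exception hierarchy for phenomap.

All errors derive from :class:`PhenomapError` so callers can catch the
package's failures with one handler while still distinguishing I/O,
geometry and numerical degeneracies.
"""


class PhenomapError(Exception):
    """Base class for all phenomap errors."""


class FormatError(PhenomapError):
    """A file does not conform to the expected on-disk format."""


class CorruptFileError(FormatError):
    """Raster payload inconsistent with its header (size/interleave)."""


class InvalidGridError(PhenomapError, ValueError):
    """Wavelength grid violates a precondition (ordering, span, range tag)."""


class EmptyRangeError(PhenomapError, ValueError):
    """A wavelength trim retained no bands."""


class DegenerateReferenceError(PhenomapError, ValueError):
    """White and dark reference frames coincide at some band."""


class OutOfSpanError(PhenomapError, ValueError):
    """Requested wavelength falls outside the cube's grid span."""


class EmptyMaskError(PhenomapError, ValueError):
    """Segmentation produced no plant pixels."""


class PartitionError(PhenomapError, ValueError):
    """Region partition impossible (fewer pixels than regions)."""


class SplitError(PhenomapError, ValueError):
    """Calibration/validation split left one side empty."""

class InvalidTableError(PhenomapError, ValueError):
    """Compound reference table contains invalid entries."""


class DegenerateSpectrumError(PhenomapError, ValueError):
    """A row-wise pretreatment hit a zero denominator (constant spectrum)."""


class DegenerateTargetError(PhenomapError, ValueError):
    """Response vector has zero variance."""


class RankError(PhenomapError, ValueError):
    """More latent variables requested than the data's rank supports."""


class GridMismatchError(PhenomapError, ValueError):
    """Input wavelength grid differs from the model's grid."""


class SelectionError(PhenomapError, ValueError):
    """Band selection empty or otherwise unusable."""


class InsufficientRowsError(PhenomapError, ValueError):
    """Too few calibration rows to retain any AC coefficient."""


class EmptyMapError(PhenomapError, ValueError):
    """Chemical image has no valid pixels."""


class ConfigError(PhenomapError, ValueError):
    """Run configuration failed validation."""


class PipelineStageError(PhenomapError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
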