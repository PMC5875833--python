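"""Exception hierarchy for the focal-spot measurement pipeline."""


class FocalSpotError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(FocalSpotError):
    """A projection factor is undefined for the given source-to-plane distances."""


class EpidIOError(FocalSpotError):
    """Base class for image/report I/O errors."""


class MissingAttributeError(EpidIOError):
    """A required DICOM attribute or sidecar key is absent."""

    def __init__(self, attribute: str, source: str = ""):
        self.attribute = attribute
        msg = f"required attribute {attribute!r} is missing"
        if source:
            msg += f" in {source}"
        super().__init__(msg)


class AngleNotSupportedError(EpidIOError):
    """Collimator angle is not within tolerance of 90 or 270 degrees."""


class SidecarError(EpidIOError):
    """Raw-image metadata sidecar is malformed."""


class AnalysisError(FocalSpotError):
    """Base class for field-analysis failures."""


class DegenerateImageError(AnalysisError):
    """Image has no intensity range (constant pixel values)."""


class NoFieldError(AnalysisError):
    """No above-threshold region of plausible size was found."""


class FieldClippedError(AnalysisError):
    """The radiation field touches the detector border; centre is unreliable."""


class FieldOutOfFrameError(FocalSpotError):
    """A simulated aperture would project (partly) outside the detector grid."""


class AxisMappingError(AnalysisError):
    """The jaw-axis to detector-axis pairing could not be resolved."""


class IonChamberError(FocalSpotError):
    """Base class for ion-chamber method errors."""


class InsufficientPointsError(IonChamberError):
    """Too few scan points for a sensitivity fit."""


class ZeroSensitivityError(IonChamberError):
    """Chamber sensitivity is zero; charge differences carry no positional signal."""
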