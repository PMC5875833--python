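"""EPID image containers and I/O (DICOM RT Image, raw 16-bit + YAML sidecar).

The measurement consumes four integrated portal images: a jaw-defined and an
MLC-defined 10x10 field, each acquired at collimator 90 deg and 270 deg.
Images arrive either as DICOM RT Image objects or as 16-bit grayscale
PNG/TIFF rasters with a YAML metadata sidecar (the fixture dialect written
by the simulator).

Detector coordinates: origin at the geometric centre of the pixel grid,
pixel centres at ``(index + 0.5 - N/2) * pitch``; ``u`` runs along columns,
``v`` along rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
import yaml
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import AngleNotSupportedError, MissingAttributeError, SidecarError

RT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"

#: Native pixel pitches (mm) of the supported amorphous-silicon panels.
SUPPORTED_PITCHES = (0.784, 0.392)

JAW = "JAW"
MLC = "MLC"


@dataclass
class EpidImage:
    """One integrated portal image plus its acquisition metadata.

    Attributes
    ----------
    pixels : ndarray
        2-D intensity matrix, row-major, detector frame. Finite, >= 0.
    pixel_pitch : float
        Detector-plane pixel spacing in mm (isotropic).
    sid : float
        Source-to-imager distance in mm.
    collimator_angle : int
        90 or 270 degrees.
    defining_system : str
        ``"JAW"`` or ``"MLC"`` — which collimator shapes the field.
    source_tag : str
        Free-text provenance (usually the file of origin).
    """

    pixels: np.ndarray
    pixel_pitch: float
    sid: float
    collimator_angle: int
    defining_system: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixels must be finite and non-negative")
        if self.collimator_angle not in (90, 270):
            raise AngleNotSupportedError(
                f"collimator angle must be 90 or 270, got {self.collimator_angle}"
            )
        if self.defining_system not in (JAW, MLC):
            raise ValueError(f"defining_system must be 'JAW' or 'MLC', got {self.defining_system!r}")
        if not any(abs(self.pixel_pitch - p) < 1e-6 for p in SUPPORTED_PITCHES):
            warnings.warn(
                f"pixel pitch {self.pixel_pitch} mm is not a native panel pitch "
                f"{SUPPORTED_PITCHES}; proceeding",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MeasurementSet:
    """The four images of one focal-spot measurement (jaw/MLC x 90/270 deg)."""

    jaw_90: EpidImage
    jaw_270: EpidImage
    mlc_90: EpidImage
    mlc_270: EpidImage

    def __post_init__(self) -> None:
        slots = {
            "jaw_90": (JAW, 90),
            "jaw_270": (JAW, 270),
            "mlc_90": (MLC, 90),
            "mlc_270": (MLC, 270),
        }
        ref = self.jaw_90
        for name, (system, angle) in slots.items():
            img: EpidImage = getattr(self, name)
            if img.defining_system != system or img.collimator_angle != angle:
                raise ValueError(
                    f"slot {name} expects {system}@{angle} deg, got "
                    f"{img.defining_system}@{img.collimator_angle}"
                )
            if abs(img.pixel_pitch - ref.pixel_pitch) > 1e-9:
                raise ValueError("all four images must share one pixel pitch")
            if abs(img.sid - ref.sid) > 0.1:
                raise ValueError("all four images must share one SID (0.1 mm tolerance)")

    @property
    def sid(self) -> float:
        return self.jaw_90.sid

    @property
    def pixel_pitch(self) -> float:
        return self.jaw_90.pixel_pitch

    def images(self) -> dict[str, EpidImage]:
        return {
            "jaw_90": self.jaw_90,
            "jaw_270": self.jaw_270,
            "mlc_90": self.mlc_90,
            "mlc_270": self.mlc_270,
        }


def _nearest_supported_angle(angle: float) -> int:
    for target in (90, 270):
        if abs(float(angle) - target) <= 2.0:
            return target
    raise AngleNotSupportedError(
        f"collimator angle {angle} deg is not within 2 deg of 90 or 270"
    )


def read_dicom_rt_image(path, defining_system: str | None = None) -> EpidImage:
    """Read an RT Image DICOM file into an :class:`EpidImage`.

    Pixel values are rescaled by slope/intercept when present. The pixel
    pitch is taken from ImagePlanePixelSpacing (already at the detector
    plane); if only PixelSpacing is present it is scaled from isocenter to
    the detector plane by SID/SAD with a warning. ``defining_system``
    overrides the RTImageLabel tag (which the simulator writes).
    """
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise MissingAttributeError("PixelData", str(path))
    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept

    if "RTImageSID" not in ds:
        raise MissingAttributeError("RTImageSID", str(path))
    sid = float(ds.RTImageSID)

    if "ImagePlanePixelSpacing" in ds:
        pitch = float(ds.ImagePlanePixelSpacing[0])
    elif "PixelSpacing" in ds:
        sad = float(getattr(ds, "RadiationMachineSAD", 1000.0))
        pitch = float(ds.PixelSpacing[0]) * sid / sad
        warnings.warn(
            "ImagePlanePixelSpacing absent; scaled PixelSpacing from isocenter "
            "to the detector plane",
            stacklevel=2,
        )
    else:
        raise MissingAttributeError("ImagePlanePixelSpacing", str(path))

    if "BeamLimitingDeviceAngle" not in ds:
        raise MissingAttributeError("BeamLimitingDeviceAngle", str(path))
    angle = _nearest_supported_angle(ds.BeamLimitingDeviceAngle)

    if defining_system is None:
        label = str(getattr(ds, "RTImageLabel", "")).upper()
        if JAW in label:
            defining_system = JAW
        elif MLC in label:
            defining_system = MLC
        else:
            raise MissingAttributeError("RTImageLabel (or explicit defining_system)", str(path))

    return EpidImage(
        pixels=pixels,
        pixel_pitch=pitch,
        sid=sid,
        collimator_angle=angle,
        defining_system=defining_system,
        source_tag=str(path),
    )


def write_dicom_rt_image(image: EpidImage, path) -> None:
    """Write an :class:`EpidImage` as an RT Image DICOM file.

    Pixels are stored as unsigned 16-bit; values must already be integral
    counts in [0, 65535] (the simulator quantises on render), so the
    write/read round trip is bit-exact.
    """
    arr = np.asarray(image.pixels)
    if np.any(arr < 0) or np.any(arr > 65535) or not np.allclose(arr, np.round(arr)):
        raise ValueError("pixels must be integral counts in [0, 65535] for 16-bit storage")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = RT_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.RTImageLabel = image.defining_system
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.ImagePlanePixelSpacing = [image.pixel_pitch, image.pixel_pitch]
    ds.RTImageSID = image.sid
    ds.RadiationMachineSAD = 1000.0
    ds.BeamLimitingDeviceAngle = image.collimator_angle
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.PixelData = arr.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


_SIDECAR_KEYS = ("pixel_pitch_mm", "sid_mm", "collimator_angle_deg", "defining_system")


def read_raw_with_sidecar(image_path, sidecar_path=None) -> EpidImage:
    """Read a 16-bit grayscale PNG/TIFF plus its YAML metadata sidecar.

    The sidecar (default: image path with a ``.yaml`` suffix) must define
    ``pixel_pitch_mm``, ``sid_mm``, ``collimator_angle_deg`` and
    ``defining_system``.
    """
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".yaml")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise SidecarError(f"sidecar {sidecar_path} is not a mapping")
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise SidecarError(f"sidecar {sidecar_path} is missing keys: {missing}")
    pixels = np.asarray(iio.imread(image_path), dtype=float)
    return EpidImage(
        pixels=pixels,
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        sid=float(meta["sid_mm"]),
        collimator_angle=_nearest_supported_angle(meta["collimator_angle_deg"]),
        defining_system=str(meta["defining_system"]).upper(),
        source_tag=str(image_path),
    )


def write_raw_with_sidecar(image: EpidImage, image_path, sidecar_path=None) -> None:
    """Write a 16-bit raster (PNG or TIFF by suffix) plus its YAML sidecar."""
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".yaml")
    arr = np.asarray(image.pixels)
    if np.any(arr < 0) or np.any(arr > 65535) or not np.allclose(arr, np.round(arr)):
        raise ValueError("pixels must be integral counts in [0, 65535] for 16-bit storage")
    iio.imwrite(image_path, arr.astype(np.uint16))
    meta = {
        "pixel_pitch_mm": float(image.pixel_pitch),
        "sid_mm": float(image.sid),
        "collimator_angle_deg": int(image.collimator_angle),
        "defining_system": image.defining_system,
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_measurement_set(paths: dict[str, object]) -> MeasurementSet:
    """Assemble a :class:`MeasurementSet` from four file paths.

    ``paths`` maps slot names (``jaw_90``, ``jaw_270``, ``mlc_90``,
    ``mlc_270``) to DICOM or raster files; format is chosen by suffix.
    """
    images = {}
    for slot, path in paths.items():
        system = JAW if slot.startswith("jaw") else MLC
        p = Path(path)
        if p.suffix.lower() in (".dcm", ".dicom", ""):
            images[slot] = read_dicom_rt_image(p, defining_system=system)
        else:
            images[slot] = read_raw_with_sidecar(p)
    return MeasurementSet(**images)
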