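"""Projection geometry of the two-collimator focal-spot measurement.

A linac's jaws and MLC sit at different distances from the x-ray target. A
lateral displacement ``s`` of the beam focal spot from the collimator
rotation axis therefore projects the centres of jaw-defined and MLC-defined
fields to *different* points on the portal imager: each centre moves by
``-s * (d_epi - d_col) / d_col`` for a collimation plane at distance
``d_col`` from the source. The separation of the two projected centres,
multiplied by a machine-specific proportionality factor

    a = 1 / ((d_epi - d_jaw)/d_jaw - (d_epi - d_mlc)/d_mlc)

recovers ``s`` exactly. This module holds that algebra, the lever arm of the
half-blocked-field ion-chamber cross-check, and the geometry container.

All lengths are millimetres internally; the YAML config may declare ``cm``
and is converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import yaml

from .errors import DegenerateGeometryError

JawAxis = Literal["X", "Y"]

#: Offset magnitudes beyond this are flagged as implausible for a steered beam.
IMPLAUSIBLE_OFFSET_MM = 5.0


@dataclass(frozen=True)
class LinacGeometry:
    """Source-to-plane distances defining the projection, in mm.

    Parameters
    ----------
    d_epi : float
        Source (focal spot) to EPID detector plane.
    d_jaw_x, d_jaw_y : float
        Source to the X-jaw and Y-jaw planes.
    d_mlc : float
        Source to the MLC plane.
    d_ic : float
        Source to the collimator-mounted ion chamber (cross-check method).
    sad : float
        Source-to-isocenter distance, default 1000 mm.
    """

    d_epi: float = 1000.0
    d_jaw_x: float = 406.0
    d_jaw_y: float = 319.0
    d_mlc: float = 490.0
    d_ic: float = 750.0
    sad: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("d_epi", "d_jaw_x", "d_jaw_y", "d_mlc", "d_ic", "sad"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("d_jaw_x", "d_jaw_y", "d_mlc", "d_ic"):
            if not getattr(self, name) < self.d_epi:
                raise ValueError(f"{name} must be below the detector plane (d_epi)")
        if self.d_mlc == self.d_jaw_x or self.d_mlc == self.d_jaw_y:
            raise ValueError("d_mlc must differ from both jaw distances")
        if self.d_ic <= self.d_jaw_x or self.d_ic <= self.d_jaw_y:
            raise ValueError("the ion chamber must sit below both jaw planes")

    def d_jaw(self, axis: JawAxis) -> float:
        """Source-to-jaw distance for the selected jaw pair."""
        if axis == "X":
            return self.d_jaw_x
        if axis == "Y":
            return self.d_jaw_y
        raise ValueError(f"jaw axis must be 'X' or 'Y', got {axis!r}")

    def with_sid(self, sid: float) -> "LinacGeometry":
        """Copy of this geometry with the detector at a different SID."""
        return replace(self, d_epi=float(sid))


@dataclass(frozen=True)
class OffsetVector:
    """Focal-spot offset relative to the collimator rotation axis, mm.

    ``crossplane`` is positive toward the detector column-increasing
    direction; ``inplane`` is positive toward the gun (detector
    row-decreasing direction).
    """

    crossplane: float
    inplane: float

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.crossplane) and math.isfinite(self.inplane)):
            raise ValueError("offset components must be finite")
        mag = math.hypot(self.crossplane, self.inplane)
        if mag >= IMPLAUSIBLE_OFFSET_MM:
            warnings.warn(
                f"focal-spot offset magnitude {mag:.2f} mm exceeds "
                f"{IMPLAUSIBLE_OFFSET_MM:g} mm and is implausible for a steered beam",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CentroidSeparation:
    """Signed MLC-minus-jaw field-centroid separation at the detector, mm."""

    axis: str  # detector axis label, "u" (columns) or "v" (rows)
    value: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.value):
            raise ValueError("separation must be finite")


def proportionality_factor(geometry: LinacGeometry, jaw_axis: JawAxis) -> float:
    """Factor *a* converting detector-plane centroid separation to offset.

    ``a = 1 / ((d_epi - d_jaw)/d_jaw - (d_epi - d_mlc)/d_mlc)`` — positive
    when the jaws sit above the MLC, so that the MLC-minus-jaw separation
    times *a* equals the focal-spot offset.
    """
    d_jaw = geometry.d_jaw(jaw_axis)
    denom = (geometry.d_epi - d_jaw) / d_jaw - (geometry.d_epi - geometry.d_mlc) / geometry.d_mlc
    if abs(denom) < 1e-12:
        raise DegenerateGeometryError(
            "jaw and MLC planes are projectively indistinguishable "
            f"(denominator {denom:.3e})"
        )
    return 1.0 / denom


def offset_from_separation(sep: CentroidSeparation | float, a: float) -> float:
    """Focal-spot offset component (mm) from a centroid separation and factor."""
    value = sep.value if isinstance(sep, CentroidSeparation) else float(sep)
    return a * value


def project_center(source_offset: float, d_col: float, d_epi: float) -> float:
    """Detector-plane displacement of the centre of an axis-centred aperture.

    For an aperture centred on the collimator rotation axis at plane
    ``d_col`` and a point source displaced laterally by ``source_offset``,
    both aperture edges — hence the field centre — project to the detector
    displaced by ``-source_offset * (d_epi - d_col) / d_col``.
    """
    if not 0 < d_col < d_epi:
        raise ValueError("collimator plane must lie between source and detector")
    return -source_offset * (d_epi - d_col) / d_col


def ic_lever_arm(geometry: LinacGeometry, jaw_axis: JawAxis) -> float:
    """Similar-triangle factor ``d_ic / (d_ic - d_jaw)`` of the chamber method.

    Relates a physical jaw-plane shift of the half-blocking jaw to the
    equivalent lateral source displacement seen by a chamber at ``d_ic``.
    """
    d_jaw = geometry.d_jaw(jaw_axis)
    if geometry.d_ic <= d_jaw:
        raise DegenerateGeometryError("ion chamber must sit below the jaw plane")
    return geometry.d_ic / (geometry.d_ic - d_jaw)


def jaw_plane_shift(shift_at_iso: float, d_jaw: float, sad: float) -> float:
    """Convert a jaw shift expressed at isocenter level to the physical jaw plane."""
    if sad <= 0:
        raise ValueError("sad must be positive")
    return shift_at_iso * d_jaw / sad


def load_geometry(path) -> LinacGeometry:
    """Read a geometry config from YAML.

    Keys: ``units`` (``mm`` or ``cm``), ``d_epi``, ``d_jaw_x``, ``d_jaw_y``,
    ``d_mlc``, ``d_ic`` and optional ``sad``. ``cm`` values are converted to
    mm on load.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"geometry config {path} is not a mapping")
    units = raw.pop("units", "mm")
    if units not in ("mm", "cm"):
        raise ValueError(f"units must be 'mm' or 'cm', got {units!r}")
    scale = 10.0 if units == "cm" else 1.0
    known = {"d_epi", "d_jaw_x", "d_jaw_y", "d_mlc", "d_ic", "sad"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    return LinacGeometry(**{k: float(v) * scale for k, v in raw.items()})
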