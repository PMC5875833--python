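"""Forward simulator: portal images and chamber charges with known ground truth.

The simulator shares its projection algebra with :mod:`focalspot.geometry`:
each rectangular aperture edge, at its collimation plane (nominal position
plus any per-bank miscalibration), is projected through a point source
displaced laterally by the configured true offset onto the detector plane,

    x_det = e * d_epi / d_col  -  s * (d_epi - d_col) / d_col,

where ``e`` is the edge position in the rotated (room-frame) collimator
plane and ``s`` the source offset along that detector axis. The field is the
product of error-function-smoothed step profiles per edge (a single
detector-plane penumbra sigma), multiplied by relative Gaussian noise, then
quantised to 16-bit counts so that written fixtures round-trip bit-exactly.

Collimator rotation is an axis swap with a sign flip: with the detector
axes (u = columns, v = rows), collimator 90° maps collimator-frame
``(x_c, y_c)`` to ``(-y_c, +x_c)`` and collimator 270° to ``(+y_c, -x_c)``.
Aperture decentring therefore changes sign between the two angles while the
source term does not, which is exactly why the 90°/270° pair average
isolates the focal-spot offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import erf

from .errors import FieldOutOfFrameError
from .geometry import LinacGeometry, OffsetVector, ic_lever_arm, jaw_plane_shift
from .image import (
    JAW,
    MLC,
    EpidImage,
    MeasurementSet,
    write_dicom_rt_image,
    write_raw_with_sidecar,
)
from .ionchamber import IcReading, IcScan

#: Full-scale detector counts for a fully open pixel before noise.
FULL_SCALE_COUNTS = 60000


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration of one simulated measurement.

    Lengths in mm. ``true_offset`` follows the reporting convention
    (crossplane positive toward column-increasing u, inplane positive
    toward the gun / row-decreasing v). Per-bank miscalibrations are
    physical shifts *at the collimator plane* of the X1/X2/Y1/Y2 jaws and
    the two MLC leaf banks. ``noise`` is the relative sigma of
    multiplicative Gaussian noise per pixel.
    """

    geometry: LinacGeometry = field(default_factory=LinacGeometry)
    true_offset: OffsetVector = field(default_factory=lambda: OffsetVector(0.0, 0.0))
    field_size_at_iso: float = 100.0
    penumbra_sigma: float = 1.0
    miscal_x1: float = 0.0
    miscal_x2: float = 0.0
    miscal_y1: float = 0.0
    miscal_y2: float = 0.0
    miscal_mlc_a: float = 0.0
    miscal_mlc_b: float = 0.0
    noise: float = 0.005
    pixel_pitch: float = 0.784
    grid: tuple[int, int] = (384, 512)  # rows, cols
    seed: int = 0
    ic_base_charge: float = 50.0  # nC per 100 MU, half-blocked
    ic_sensitivity: float = -2.0  # nC per mm jaw shift at isocenter
    ic_noise: float = 0.0  # absolute nC

    def __post_init__(self) -> None:
        if self.penumbra_sigma < 0 or self.noise < 0 or self.ic_noise < 0:
            raise ValueError("penumbra_sigma, noise and ic_noise must be >= 0")
        if self.field_size_at_iso <= 0:
            raise ValueError("field_size_at_iso must be positive")
        if self.ic_sensitivity == 0:
            raise ValueError("ic_sensitivity must be nonzero")


def _source_uv(cfg: SimConfig) -> tuple[float, float]:
    # crossplane -> +u; inplane positive toward gun -> -v
    return cfg.true_offset.crossplane, -cfg.true_offset.inplane


def _collimator_edges(cfg: SimConfig, defining_system: str):
    """Aperture edges in the collimator frame: (axis, d_plane, lo, hi)."""
    g = cfg.geometry
    half_iso = cfg.field_size_at_iso / 2.0
    if defining_system == JAW:
        hx = half_iso * g.d_jaw_x / g.sad
        hy = half_iso * g.d_jaw_y / g.sad
        return [
            ("x", g.d_jaw_x, -hx + cfg.miscal_x1, hx + cfg.miscal_x2),
            ("y", g.d_jaw_y, -hy + cfg.miscal_y1, hy + cfg.miscal_y2),
        ]
    hm = half_iso * g.d_mlc / g.sad
    return [
        # leaf-travel direction carries the bank miscalibration
        ("x", g.d_mlc, -hm + cfg.miscal_mlc_a, hm + cfg.miscal_mlc_b),
        # leaf-side direction: outermost closed leaves, nominal
        ("y", g.d_mlc, -hm, hm),
    ]


def _project_edge(e_room: float, d_plane: float, d_epi: float, s_axis: float) -> float:
    return e_room * d_epi / d_plane - s_axis * (d_epi - d_plane) / d_plane


def detector_edges(cfg: SimConfig, defining_system: str, collimator_angle: int):
    """Projected detector-plane edge positions ``{"u": (lo, hi), "v": (lo, hi)}``."""
    if collimator_angle not in (90, 270):
        raise ValueError("collimator angle must be 90 or 270")
    s_u, s_v = _source_uv(cfg)
    d_epi = cfg.geometry.d_epi
    out: dict[str, tuple[float, float]] = {}
    for axis_c, d_plane, lo, hi in _collimator_edges(cfg, defining_system):
        # rotation: 90 deg -> (x_c, y_c) -> (-y_c, +x_c); 270 deg -> (+y_c, -x_c)
        if collimator_angle == 90:
            det_axis, sign = ("v", +1.0) if axis_c == "x" else ("u", -1.0)
        else:
            det_axis, sign = ("v", -1.0) if axis_c == "x" else ("u", +1.0)
        s_axis = s_u if det_axis == "u" else s_v
        e1 = _project_edge(sign * lo, d_plane, d_epi, s_axis)
        e2 = _project_edge(sign * hi, d_plane, d_epi, s_axis)
        out[det_axis] = (min(e1, e2), max(e1, e2))
    return out


def analytic_center(cfg: SimConfig, defining_system: str, collimator_angle: int):
    """Exact (u, v) field centre in detector mm for one simulated image."""
    edges = detector_edges(cfg, defining_system, collimator_angle)
    return (
        (edges["u"][0] + edges["u"][1]) / 2.0,
        (edges["v"][0] + edges["v"][1]) / 2.0,
    )


def _image_rng(cfg: SimConfig, defining_system: str, collimator_angle: int):
    tag = {JAW: 0, MLC: 1}[defining_system] * 2 + {90: 0, 270: 1}[collimator_angle]
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def render_image(cfg: SimConfig, defining_system: str, collimator_angle: int) -> EpidImage:
    """Render one integrated portal image, quantised to 16-bit counts."""
    nrows, ncols = cfg.grid
    pitch = cfg.pixel_pitch
    u = (np.arange(ncols) + 0.5 - ncols / 2.0) * pitch
    v = (np.arange(nrows) + 0.5 - nrows / 2.0) * pitch
    edges = detector_edges(cfg, defining_system, collimator_angle)

    margin = 3.0 * cfg.penumbra_sigma + pitch
    if (
        edges["u"][0] - margin < u[0]
        or edges["u"][1] + margin > u[-1]
        or edges["v"][0] - margin < v[0]
        or edges["v"][1] + margin > v[-1]
    ):
        raise FieldOutOfFrameError(
            f"{defining_system}@{collimator_angle} field {edges} exceeds the "
            f"{nrows}x{ncols} grid at {pitch} mm pitch"
        )

    def profile(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if cfg.penumbra_sigma == 0:
            return ((x >= lo) & (x <= hi)).astype(float)
        s2 = cfg.penumbra_sigma * np.sqrt(2.0)
        return 0.25 * (1.0 + erf((x - lo) / s2)) * (1.0 + erf((hi - x) / s2))

    intensity = np.outer(profile(v, *edges["v"]), profile(u, *edges["u"]))
    if cfg.noise > 0:
        rng = _image_rng(cfg, defining_system, collimator_angle)
        intensity = intensity * (1.0 + cfg.noise * rng.standard_normal(intensity.shape))
    counts = np.clip(np.round(intensity * FULL_SCALE_COUNTS), 0, 65535)
    return EpidImage(
        pixels=counts,
        pixel_pitch=pitch,
        sid=cfg.geometry.d_epi,
        collimator_angle=collimator_angle,
        defining_system=defining_system,
        source_tag=f"sim:{defining_system}@{collimator_angle}",
    )


def render_measurement_set(
    cfg: SimConfig, out_dir=None, fmt: str = "raw"
) -> MeasurementSet:
    """Render the four-image set; optionally write it plus a truth manifest.

    ``fmt`` is ``"raw"`` (16-bit PNG + YAML sidecar) or ``"dicom"``. The
    ground truth goes into ``manifest.json`` beside the images, never into
    the image files themselves.
    """
    mset = MeasurementSet(
        jaw_90=render_image(cfg, JAW, 90),
        jaw_270=render_image(cfg, JAW, 270),
        mlc_90=render_image(cfg, MLC, 90),
        mlc_270=render_image(cfg, MLC, 270),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for slot, img in mset.images().items():
            if fmt == "dicom":
                write_dicom_rt_image(img, out_dir / f"{slot}.dcm")
            elif fmt == "raw":
                write_raw_with_sidecar(img, out_dir / f"{slot}.png")
            else:
                raise ValueError(f"format must be 'raw' or 'dicom', got {fmt!r}")
        g = cfg.geometry
        manifest = {
            "true_offset_mm": {
                "crossplane": cfg.true_offset.crossplane,
                "inplane": cfg.true_offset.inplane,
            },
            "seed": cfg.seed,
            "format": fmt,
            "field_size_at_iso_mm": cfg.field_size_at_iso,
            "penumbra_sigma_mm": cfg.penumbra_sigma,
            "noise_relative_sigma": cfg.noise,
            "pixel_pitch_mm": cfg.pixel_pitch,
            "grid": list(cfg.grid),
            "miscalibration_mm": {
                "x1": cfg.miscal_x1,
                "x2": cfg.miscal_x2,
                "y1": cfg.miscal_y1,
                "y2": cfg.miscal_y2,
                "mlc_a": cfg.miscal_mlc_a,
                "mlc_b": cfg.miscal_mlc_b,
            },
            "geometry_mm": {
                "d_epi": g.d_epi,
                "d_jaw_x": g.d_jaw_x,
                "d_jaw_y": g.d_jaw_y,
                "d_mlc": g.d_mlc,
                "d_ic": g.d_ic,
                "sad": g.sad,
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return mset


def _offset_along_jaw(cfg: SimConfig, jaw_axis: str) -> float:
    """True source-offset component measured by the given half-blocking jaw.

    With the default axis pairing the X jaws travel along the inplane
    direction and the Y jaws along crossplane.
    """
    if jaw_axis == "X":
        return cfg.true_offset.inplane
    if jaw_axis == "Y":
        return cfg.true_offset.crossplane
    raise ValueError(f"jaw_axis must be 'X' or 'Y', got {jaw_axis!r}")


def simulate_ic(cfg: SimConfig, jaw_axis: str) -> tuple[IcScan, IcReading]:
    """Chamber sensitivity scan plus paired 90°/270° readings.

    Charge is linear in the half-blocking jaw's alignment with the source
    (first-order model about the half-blocked position): the scan shifts the
    jaw with the source fixed; the paired readings see the true offset as an
    equivalent jaw shift whose sign flips with the 180° collimator rotation.
    """
    g = cfg.geometry
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    shifts = np.linspace(-1.5, 1.5, 7)
    charges = cfg.ic_base_charge + cfg.ic_sensitivity * shifts
    if cfg.ic_noise > 0:
        charges = charges + cfg.ic_noise * rng.standard_normal(shifts.shape)
    scan = IcScan(shifts_mm=shifts, charges_nc=charges, jaw_axis=jaw_axis)

    s = _offset_along_jaw(cfg, jaw_axis)
    d_jaw = g.d_jaw(jaw_axis)
    # equivalent jaw shift at iso level seen by the chamber for source offset s:
    # invert offset = lever * jaw_plane_shift(z_iso)
    z_iso = s / (ic_lever_arm(g, jaw_axis) * (d_jaw / g.sad))
    dq = cfg.ic_sensitivity * z_iso
    noise = cfg.ic_noise * rng.standard_normal(2) if cfg.ic_noise > 0 else np.zeros(2)
    reading = IcReading(
        q_90=cfg.ic_base_charge + dq + noise[0],
        q_270=cfg.ic_base_charge - dq + noise[1],
        jaw_axis=jaw_axis,
    )
    return scan, reading
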