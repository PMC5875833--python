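"""Field-centre extraction and the four-image focal-spot measurement.

Each portal image is median-filtered, min–max scaled to [0, 1], bicubically
upsampled to a common 0.0392 mm effective pitch, and binarised at the 50%
level (the half-value full-width definition of the radiation field edge).
The field centre is the mean, over rows in a central band, of the midpoint
between the two 50%-intensity edge crossings; the crossing position is
refined to sub-pixel accuracy by linear interpolation across the binary
boundary. Averaging the centres of the collimator-90° and -270° images
cancels aperture (jaw/MLC bank) miscalibration; the remaining jaw-vs-MLC
centroid separation, scaled by the geometry factor *a*, is the focal-spot
offset.

:class:`FocalSpotModel` wraps the whole procedure in a model/results pair:
build it from a :class:`~focalspot.image.MeasurementSet` and a
:class:`~focalspot.geometry.LinacGeometry`, call :meth:`~FocalSpotModel.fit`,
and read the offset, per-image centres and diagnostics off the returned
:class:`FocalSpotResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import (
    AxisMappingError,
    DegenerateImageError,
    FieldClippedError,
    NoFieldError,
)
from .geometry import (
    CentroidSeparation,
    LinacGeometry,
    OffsetVector,
    proportionality_factor,
)
from .image import EpidImage, MeasurementSet

AxisPairing = Literal["x-inplane", "x-crossplane"]

#: Fraction of the frame a plausible field region may occupy.
_MIN_REGION_FRACTION = 0.01
_MAX_REGION_FRACTION = 0.90


@dataclass(frozen=True)
class AnalysisParams:
    """Tunables of the image algorithm.

    median_kernel : odd window size (pixels) of the 2-D median noise filter.
    threshold : binarisation level on the min–max scaled image; 0.5 is the
        half-value full-width field-edge definition.
    target_effective_pitch : mm; the upsample factor is
        ``round(pixel_pitch / target_effective_pitch)`` so all panels reach
        a common computation grid (×20 for 0.784 mm, ×10 for 0.392 mm).
    edge_band_fraction : central fraction of the field extent whose rows
        (columns) contribute to the edge average; excludes corner penumbra
        and MLC leaf-end scallop.
    """

    median_kernel: int = 3
    threshold: float = 0.5
    target_effective_pitch: float = 0.0392
    edge_band_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be a positive odd integer")
        if not 0 < self.edge_band_fraction <= 1:
            raise ValueError("edge_band_fraction must be in (0, 1]")
        if self.target_effective_pitch <= 0:
            raise ValueError("target_effective_pitch must be positive")


@dataclass(frozen=True)
class FieldCenter:
    """Field centre in detector mm (centred origin): u along columns, v along rows."""

    u: float
    v: float
    source_tag: str = ""


def preprocess(image: EpidImage, params: AnalysisParams | None = None) -> tuple[np.ndarray, float]:
    """Median-filter, min–max normalise and bicubically upsample one image.

    Returns the upsampled unit-scaled matrix and its effective pixel pitch
    (``pixel_pitch / factor``).
    """
    params = params or AnalysisParams()
    filtered = ndimage.median_filter(image.pixels, size=params.median_kernel)
    lo, hi = float(filtered.min()), float(filtered.max())
    if hi - lo <= 0:
        raise DegenerateImageError("image is constant after filtering; no field present")
    normed = (filtered - lo) / (hi - lo)
    factor = int(round(image.pixel_pitch / params.target_effective_pitch))
    if factor < 1:
        factor = 1
    out_shape = (normed.shape[0] * factor, normed.shape[1] * factor)
    up = resize(normed, out_shape, order=3, mode="edge", anti_aliasing=False)
    return up, image.pixel_pitch / factor


def _edge_positions(P: np.ndarray, comp: np.ndarray, rows: np.ndarray, threshold: float, axis: int):
    """Sub-pixel low/high 50%-crossing positions (index units) per band line.

    ``comp`` is the binary field mask; lines are rows (``axis=1``: crossings
    along columns) or columns (``axis=0``: crossings along rows). The
    crossing is interpolated linearly between the last below-threshold pixel
    outside the field and the first above-threshold pixel inside it.
    """
    if axis == 1:
        band = comp[rows[0] : rows[-1] + 1]
        n = P.shape[1]
        i0 = band.argmax(axis=1)
        i1 = n - 1 - band[:, ::-1].argmax(axis=1)
        prev, cur = P[rows, i0 - 1], P[rows, i0]
        nxt, cur_r = P[rows, i1 + 1], P[rows, i1]
    else:
        band = comp[:, rows[0] : rows[-1] + 1]
        n = P.shape[0]
        i0 = band.argmax(axis=0)
        i1 = n - 1 - band[::-1].argmax(axis=0)
        prev, cur = P[i0 - 1, rows], P[i0, rows]
        nxt, cur_r = P[i1 + 1, rows], P[i1, rows]

    dl = cur - prev
    frac_l = np.where(dl > 0, (threshold - prev) / np.where(dl > 0, dl, 1.0), 0.5)
    low = (i0 - 1) + np.clip(frac_l, 0.0, 1.0)

    dr = cur_r - nxt
    frac_r = np.where(dr > 0, (cur_r - threshold) / np.where(dr > 0, dr, 1.0), 0.5)
    high = i1 + np.clip(frac_r, 0.0, 1.0)
    return low, high


def find_field_center(
    processed: np.ndarray,
    effective_pitch: float,
    params: AnalysisParams | None = None,
    source_tag: str = "",
) -> FieldCenter:
    """Locate the field centre of a preprocessed (unit-scaled, upsampled) image.

    The image is binarised at ``params.threshold`` (ties count as field);
    the largest connected above-threshold region is taken as the radiation
    field. For each row in the central ``edge_band_fraction`` of the field's
    vertical extent, the left/right 50% crossings are averaged to a row
    centre; row centres are averaged to the ``u`` centre, and symmetrically
    for ``v``. Positions are converted to mm with pixel centres at
    ``(index + 0.5 - N/2) * effective_pitch``.
    """
    params = params or AnalysisParams()
    P = np.asarray(processed, dtype=float)
    nrows, ncols = P.shape
    mask = P >= params.threshold
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        raise NoFieldError("no above-threshold region found")
    sizes = np.bincount(labels.ravel())[1:]
    lab = int(np.argmax(sizes)) + 1
    frac = sizes[lab - 1] / mask.size
    if not _MIN_REGION_FRACTION <= frac <= _MAX_REGION_FRACTION:
        raise NoFieldError(
            f"largest region covers {frac:.1%} of the frame, outside "
            f"[{_MIN_REGION_FRACTION:.0%}, {_MAX_REGION_FRACTION:.0%}]"
        )
    comp = labels == lab
    row_any = comp.any(axis=1)
    col_any = comp.any(axis=0)
    r_min, r_max = int(row_any.argmax()), nrows - 1 - int(row_any[::-1].argmax())
    c_min, c_max = int(col_any.argmax()), ncols - 1 - int(col_any[::-1].argmax())
    if r_min == 0 or r_max == nrows - 1 or c_min == 0 or c_max == ncols - 1:
        raise FieldClippedError("field region touches the detector border")

    def band(lo: int, hi: int) -> np.ndarray:
        extent = hi - lo + 1
        margin = (1.0 - params.edge_band_fraction) / 2.0 * extent
        b_lo = lo + int(np.ceil(margin))
        b_hi = hi - int(np.ceil(margin))
        if b_hi < b_lo:  # degenerate: fall back to full extent
            b_lo, b_hi = lo, hi
        return np.arange(b_lo, b_hi + 1)

    rows = band(r_min, r_max)
    left, right = _edge_positions(P, comp, rows, params.threshold, axis=1)
    u_idx = float(np.mean((left + right) / 2.0))

    cols = band(c_min, c_max)
    top, bot = _edge_positions(P, comp, cols, params.threshold, axis=0)
    v_idx = float(np.mean((top + bot) / 2.0))

    u = (u_idx + 0.5 - ncols / 2.0) * effective_pitch
    v = (v_idx + 0.5 - nrows / 2.0) * effective_pitch
    return FieldCenter(u=u, v=v, source_tag=source_tag)


def pair_centroid(center_90: FieldCenter, center_270: FieldCenter) -> FieldCenter:
    """Average the 90°/270° field centres; aperture miscalibration cancels."""
    return FieldCenter(
        u=(center_90.u + center_270.u) / 2.0,
        v=(center_90.v + center_270.v) / 2.0,
        source_tag=f"{center_90.source_tag}+{center_270.source_tag}",
    )


def centroid_separation(
    jaw_centroid: FieldCenter, mlc_centroid: FieldCenter
) -> dict[str, CentroidSeparation]:
    """MLC-minus-jaw centroid separation per detector axis, mm."""
    return {
        "u": CentroidSeparation(axis="u", value=mlc_centroid.u - jaw_centroid.u),
        "v": CentroidSeparation(axis="v", value=mlc_centroid.v - jaw_centroid.v),
    }


class FocalSpotModel:
    """Four-image focal-spot offset measurement.

    Parameters
    ----------
    measurement_set : MeasurementSet
        Jaw- and MLC-defined 10x10 fields at collimator 90° and 270°.
    geometry : LinacGeometry
        Source-to-plane distances; ``d_epi`` is overridden by the set's SID.
    params : AnalysisParams, optional
    axis_pairing : {"x-inplane", "x-crossplane"}
        Which jaw pair measures which reported direction. With the
        collimator at 90°/270° the X jaws travel along the detector row
        (inplane) direction — the default pairing.
    """

    def __init__(
        self,
        measurement_set: MeasurementSet,
        geometry: LinacGeometry,
        params: AnalysisParams | None = None,
        axis_pairing: AxisPairing = "x-inplane",
    ):
        if axis_pairing not in ("x-inplane", "x-crossplane"):
            raise AxisMappingError(
                f"axis_pairing must be 'x-inplane' or 'x-crossplane', got {axis_pairing!r}"
            )
        self.measurement_set = measurement_set
        self.geometry = geometry
        self.params = params or AnalysisParams()
        self.axis_pairing = axis_pairing

    @classmethod
    def from_files(
        cls,
        jaw_90,
        jaw_270,
        mlc_90,
        mlc_270,
        geometry: LinacGeometry,
        params: AnalysisParams | None = None,
        axis_pairing: AxisPairing = "x-inplane",
    ) -> "FocalSpotModel":
        from .image import read_measurement_set

        mset = read_measurement_set(
            {"jaw_90": jaw_90, "jaw_270": jaw_270, "mlc_90": mlc_90, "mlc_270": mlc_270}
        )
        return cls(mset, geometry, params=params, axis_pairing=axis_pairing)

    def fit(self) -> "FocalSpotResults":
        """Run the full pipeline and return the fitted results."""
        mset = self.measurement_set
        geom = self.geometry.with_sid(mset.sid)

        centers: dict[str, FieldCenter] = {}
        eff_pitch = None
        for slot, img in mset.images().items():
            processed, pitch = preprocess(img, self.params)
            centers[slot] = find_field_center(
                processed, pitch, self.params, source_tag=img.source_tag or slot
            )
            eff_pitch = pitch

        jaw_c = pair_centroid(centers["jaw_90"], centers["jaw_270"])
        mlc_c = pair_centroid(centers["mlc_90"], centers["mlc_270"])
        seps = centroid_separation(jaw_c, mlc_c)

        # u (columns) is the travel direction of whichever jaw pair is not
        # mapped to inplane; v (rows) carries the other pair. Inplane is
        # reported positive toward the gun, i.e. against row-increasing v.
        if self.axis_pairing == "x-inplane":
            jaw_for_u, jaw_for_v = "Y", "X"
        else:
            jaw_for_u, jaw_for_v = "X", "Y"
        factors = {
            "u": proportionality_factor(geom, jaw_for_u),
            "v": proportionality_factor(geom, jaw_for_v),
        }
        crossplane = factors["u"] * seps["u"].value
        inplane = -factors["v"] * seps["v"].value
        offset = OffsetVector(crossplane=crossplane, inplane=inplane)

        return FocalSpotResults(
            model=self,
            offset=offset,
            field_centers=centers,
            jaw_centroid=jaw_c,
            mlc_centroid=mlc_c,
            separations=seps,
            factors=factors,
            jaw_mapping={"u": jaw_for_u, "v": jaw_for_v},
            geometry=geom,
            effective_pitch=eff_pitch,
        )


@dataclass
class FocalSpotResults:
    """Fitted focal-spot measurement: estimate, intermediates and provenance."""

    model: FocalSpotModel
    offset: OffsetVector
    field_centers: dict[str, FieldCenter]
    jaw_centroid: FieldCenter
    mlc_centroid: FieldCenter
    separations: dict[str, CentroidSeparation]
    factors: dict[str, float]
    jaw_mapping: dict[str, str]
    geometry: LinacGeometry
    effective_pitch: float

    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "kind": "epid",
            "offset_mm": {
                "crossplane": self.offset.crossplane,
                "inplane": self.offset.inplane,
            },
            "field_centers_mm": {
                slot: {"u": c.u, "v": c.v, "source": c.source_tag}
                for slot, c in self.field_centers.items()
            },
            "jaw_centroid_mm": {"u": self.jaw_centroid.u, "v": self.jaw_centroid.v},
            "mlc_centroid_mm": {"u": self.mlc_centroid.u, "v": self.mlc_centroid.v},
            "separation_mm": {ax: s.value for ax, s in self.separations.items()},
            "factors": dict(self.factors),
            "jaw_mapping": dict(self.jaw_mapping),
            "axis_pairing": self.model.axis_pairing,
            "effective_pitch_mm": self.effective_pitch,
            "geometry_mm": {
                "d_epi": g.d_epi,
                "d_jaw_x": g.d_jaw_x,
                "d_jaw_y": g.d_jaw_y,
                "d_mlc": g.d_mlc,
                "d_ic": g.d_ic,
                "sad": g.sad,
            },
            "params": {
                "median_kernel": self.model.params.median_kernel,
                "threshold": self.model.params.threshold,
                "target_effective_pitch": self.model.params.target_effective_pitch,
                "edge_band_fraction": self.model.params.edge_band_fraction,
            },
        }

    def save(self, path) -> None:
        from .report import write_report

        write_report(self, path)

    def summary(self) -> str:
        lines = [
            "Focal-spot offset measurement (EPID, jaw-vs-MLC centroid method)",
            "=" * 66,
            f"crossplane offset : {self.offset.crossplane:+.3f} mm",
            f"inplane offset    : {self.offset.inplane:+.3f} mm",
            "-" * 66,
            f"SID               : {self.geometry.d_epi:.1f} mm",
            f"effective pitch   : {self.effective_pitch:.4f} mm",
            f"factor a (u axis) : {self.factors['u']:.4f}  ({self.jaw_mapping['u']} jaws)",
            f"factor a (v axis) : {self.factors['v']:.4f}  ({self.jaw_mapping['v']} jaws)",
            f"separation u      : {self.separations['u'].value:+.4f} mm (MLC - jaw)",
            f"separation v      : {self.separations['v'].value:+.4f} mm (MLC - jaw)",
            "-" * 66,
            "field centres (u, v) mm:",
        ]
        for slot, c in self.field_centers.items():
            lines.append(f"  {slot:<8}: ({c.u:+.4f}, {c.v:+.4f})")
        lines.append(
            f"  jaw pair : ({self.jaw_centroid.u:+.4f}, {self.jaw_centroid.v:+.4f})"
        )
        lines.append(
            f"  mlc pair : ({self.mlc_centroid.u:+.4f}, {self.mlc_centroid.v:+.4f})"
        )
        return "\n".join(lines)

    def plot_overlay(self, path=None):
        """QA overlay: the jaw-90° image with all four field centres marked."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = self.model.measurement_set.jaw_90
        n_r, n_c = img.pixels.shape
        extent = [
            (0.5 - n_c / 2) * img.pixel_pitch - 0.5 * img.pixel_pitch,
            (n_c - 0.5 - n_c / 2) * img.pixel_pitch + 0.5 * img.pixel_pitch,
            (n_r - 0.5 - n_r / 2) * img.pixel_pitch + 0.5 * img.pixel_pitch,
            (0.5 - n_r / 2) * img.pixel_pitch - 0.5 * img.pixel_pitch,
        ]
        fig, ax = plt.subplots(figsize=(7, 5.5))
        ax.imshow(img.pixels, cmap="gray", extent=extent)
        markers = {"jaw_90": "r+", "jaw_270": "rx", "mlc_90": "b+", "mlc_270": "bx"}
        for slot, c in self.field_centers.items():
            ax.plot(c.u, c.v, markers[slot], ms=12, label=slot)
        ax.plot(self.jaw_centroid.u, self.jaw_centroid.v, "ro", mfc="none", label="jaw centroid")
        ax.plot(self.mlc_centroid.u, self.mlc_centroid.v, "bo", mfc="none", label="mlc centroid")
        ax.set_xlabel("u (mm)")
        ax.set_ylabel("v (mm)")
        ax.set_title(
            f"offset: crossplane {self.offset.crossplane:+.3f} mm, "
            f"inplane {self.offset.inplane:+.3f} mm"
        )
        ax.legend(loc="upper right", fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def measure_focal_spot(
    measurement_set: MeasurementSet,
    geometry: LinacGeometry,
    params: AnalysisParams | None = None,
    axis_pairing: AxisPairing = "x-inplane",
) -> FocalSpotResults:
    """Functional wrapper: build a :class:`FocalSpotModel` and fit it."""
    return FocalSpotModel(measurement_set, geometry, params, axis_pairing).fit()
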