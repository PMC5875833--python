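"""Independent focal-spot check with a collimator-mounted ion chamber.

A chamber riding on the collimator at ``d_ic`` from the source sits behind a
half-blocking jaw. Its charge is, to first order, linear in how much of the
focal spot the jaw obscures, so:

1. calibrate the sensitivity (nC per mm of jaw travel at isocenter level)
   by scanning the half-blocking jaw and fitting an ordinary least-squares
   line to (shift, charge);
2. read the charge at collimator 90° and 270°: a focal spot centred on the
   rotation axis gives equal readings, an offset shows up as half the
   charge difference;
3. convert: equivalent iso-level jaw shift -> physical jaw-plane shift
   (``x d_jaw / sad``) -> focal-spot offset via the similar-triangle lever
   arm ``d_ic / (d_ic - d_jaw)``.

The module also provides the method-agreement statistics used to compare
this check against the portal-image method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientPointsError, IonChamberError, ZeroSensitivityError
from .geometry import JawAxis, LinacGeometry, ic_lever_arm, jaw_plane_shift

#: Below this R-squared the first-order linearity assumption is suspect.
LINEARITY_R2_WARNING = 0.95


@dataclass
class IcScan:
    """Chamber sensitivity scan: charges at known iso-level jaw shifts."""

    shifts_mm: np.ndarray
    charges_nc: np.ndarray
    jaw_axis: JawAxis

    def __post_init__(self) -> None:
        self.shifts_mm = np.asarray(self.shifts_mm, dtype=float)
        self.charges_nc = np.asarray(self.charges_nc, dtype=float)
        if self.shifts_mm.shape != self.charges_nc.shape or self.shifts_mm.ndim != 1:
            raise ValueError("shifts and charges must be 1-D arrays of equal length")
        if len(self.shifts_mm) >= 3:
            if np.ptp(self.shifts_mm) < 1.0:
                raise ValueError("scan shifts must span at least 1 mm")
            if np.any(self.charges_nc <= 0):
                raise ValueError("charges must be positive")

    @classmethod
    def from_csv(cls, path, jaw_axis: JawAxis) -> "IcScan":
        """Load a scan from CSV with columns ``shift_mm`` and ``charge_nC``."""
        df = pd.read_csv(path)
        missing = {"shift_mm", "charge_nC"} - set(df.columns)
        if missing:
            raise IonChamberError(f"scan CSV {path} is missing columns {sorted(missing)}")
        return cls(df["shift_mm"].to_numpy(), df["charge_nC"].to_numpy(), jaw_axis)


@dataclass(frozen=True)
class IcReading:
    """Paired half-blocked charges at collimator 90° and 270°, nC."""

    q_90: float
    q_270: float
    jaw_axis: JawAxis

    def __post_init__(self) -> None:
        if self.q_90 <= 0 or self.q_270 <= 0:
            raise ValueError("charges must be positive")


@dataclass(frozen=True)
class SensitivityFit:
    """OLS sensitivity of chamber charge to iso-level jaw shift."""

    slope_nc_per_mm: float
    intercept_nc: float
    r_squared: float
    residual_max_nc: float
    n: int


def sensitivity(scan: IcScan) -> SensitivityFit:
    """Least-squares chamber sensitivity (nC per mm jaw shift at isocenter).

    Warns when R-squared falls below ``LINEARITY_R2_WARNING``: the
    conversion chain rests on a first-order linear response.
    """
    if len(scan.shifts_mm) < 3:
        raise InsufficientPointsError(
            f"need at least 3 scan points, got {len(scan.shifts_mm)}"
        )
    if np.ptp(scan.shifts_mm) == 0:
        raise IonChamberError("scan shifts have zero variance")
    fit = stats.linregress(scan.shifts_mm, scan.charges_nc)
    resid = scan.charges_nc - (fit.intercept + fit.slope * scan.shifts_mm)
    r2 = fit.rvalue**2
    if r2 < LINEARITY_R2_WARNING:
        warnings.warn(
            f"sensitivity fit R^2 = {r2:.3f} < {LINEARITY_R2_WARNING}: "
            "chamber response may not be linear over this scan range",
            stacklevel=2,
        )
    return SensitivityFit(
        slope_nc_per_mm=float(fit.slope),
        intercept_nc=float(fit.intercept),
        r_squared=float(r2),
        residual_max_nc=float(np.max(np.abs(resid))),
        n=len(scan.shifts_mm),
    )


def ic_offset(
    reading: IcReading,
    sens: SensitivityFit | float,
    geometry: LinacGeometry,
) -> float:
    """Focal-spot offset component (mm) from one paired charge reading.

    Half the 90°-270° charge difference, divided by the sensitivity, is the
    equivalent jaw shift at isocenter level; scaled to the physical jaw
    plane and through the chamber lever arm it is the offset, in the same
    sign convention as the portal-image method.
    """
    slope = sens.slope_nc_per_mm if isinstance(sens, SensitivityFit) else float(sens)
    if slope == 0:
        raise ZeroSensitivityError("chamber sensitivity is zero")
    z_iso = (reading.q_90 - reading.q_270) / 2.0 / slope
    z_plane = jaw_plane_shift(z_iso, geometry.d_jaw(reading.jaw_axis), geometry.sad)
    return ic_lever_arm(geometry, reading.jaw_axis) * z_plane


@dataclass(frozen=True)
class MethodComparison:
    """Agreement statistics between chamber and portal-image offsets (mm)."""

    mean_difference: float
    sd_difference: float
    max_abs_difference: float
    n: int


def compare_methods(pairs) -> MethodComparison:
    """Chamber-minus-EPID agreement over paired measurements.

    ``pairs`` is an iterable of ``(epid_mm, ic_mm)``. Differences are
    ``ic - epid``; the SD uses the sample (n-1) denominator.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (epid, ic) tuples")
    if len(arr) < 2:
        raise InsufficientPointsError("need at least 2 pairs for a comparison SD")
    diffs = arr[:, 1] - arr[:, 0]
    return MethodComparison(
        mean_difference=float(np.mean(diffs)),
        sd_difference=float(np.std(diffs, ddof=1)),
        max_abs_difference=float(np.max(np.abs(diffs))),
        n=len(diffs),
    )


class IonChamberModel:
    """Two-axis chamber measurement: scans plus paired readings per jaw.

    With the collimator at 90°/270° the X jaws travel along the inplane
    direction and the Y jaws along crossplane (the same default pairing as
    the portal-image method).
    """

    def __init__(
        self,
        scans: dict[str, IcScan],
        readings: dict[str, IcReading],
        geometry: LinacGeometry,
    ):
        for axis in scans:
            if axis not in ("X", "Y"):
                raise ValueError(f"scan axis must be 'X' or 'Y', got {axis!r}")
        for axis, reading in readings.items():
            if axis not in scans:
                raise ValueError(f"reading for axis {axis!r} has no matching scan")
            if reading.jaw_axis != axis or scans[axis].jaw_axis != axis:
                raise ValueError(f"axis mismatch in scan/reading for {axis!r}")
        self.scans = scans
        self.readings = readings
        self.geometry = geometry

    def fit(self) -> "IonChamberResults":
        fits = {axis: sensitivity(scan) for axis, scan in self.scans.items()}
        offsets = {
            axis: ic_offset(reading, fits[axis], self.geometry)
            for axis, reading in self.readings.items()
        }
        return IonChamberResults(
            model=self,
            sensitivities=fits,
            offsets_by_jaw=offsets,
            crossplane=offsets.get("Y"),
            inplane=offsets.get("X"),
        )


@dataclass
class IonChamberResults:
    """Fitted chamber method: per-jaw sensitivities and offset components."""

    model: IonChamberModel
    sensitivities: dict[str, SensitivityFit]
    offsets_by_jaw: dict[str, float]
    crossplane: float | None
    inplane: float | None

    def to_dict(self) -> dict:
        g = self.model.geometry
        return {
            "kind": "ic",
            "offset_mm": {"crossplane": self.crossplane, "inplane": self.inplane},
            "offsets_by_jaw_mm": dict(self.offsets_by_jaw),
            "sensitivities": {
                axis: {
                    "slope_nc_per_mm": f.slope_nc_per_mm,
                    "intercept_nc": f.intercept_nc,
                    "r_squared": f.r_squared,
                    "residual_max_nc": f.residual_max_nc,
                    "n": f.n,
                }
                for axis, f in self.sensitivities.items()
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

    def save(self, path) -> None:
        from .report import write_report

        write_report(self, path)

    def summary(self) -> str:
        lines = [
            "Focal-spot offset (half-blocked-field ion-chamber method)",
            "=" * 60,
        ]
        if self.crossplane is not None:
            lines.append(f"crossplane offset : {self.crossplane:+.3f} mm  (Y jaw)")
        if self.inplane is not None:
            lines.append(f"inplane offset    : {self.inplane:+.3f} mm  (X jaw)")
        lines.append("-" * 60)
        for axis, f in self.sensitivities.items():
            lever = ic_lever_arm(self.model.geometry, axis)
            lines.append(
                f"{axis} jaw: sensitivity {f.slope_nc_per_mm:+.3f} nC/mm "
                f"(R^2 {f.r_squared:.4f}, n={f.n}), lever arm {lever:.3f}"
            )
        return "\n".join(lines)
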