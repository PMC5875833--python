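# Methods

## Measurement model

The beam is treated as emanating from a point focal spot displaced
laterally by an unknown vector from the collimator rotation axis; the axis
itself is the spatial reference. A collimator plane at distance `d_col`
from the source, holding an aperture centred on the axis, projects the
aperture centre onto the detector (at `d_epi`) at
`−s·(d_epi − d_col)/d_col` for a source offset component `s`. The jaw and
MLC planes have different `d_col`, so the two field centroids separate by

```
D_EPI = s · [ (d_epi − d_jaw)/d_jaw − (d_epi − d_mlc)/d_mlc ] = s / a
```

and multiplying the measured separation by `a` inverts the model exactly.
This first-order treatment ignores finite focal-spot size, extra-focal
radiation and flattening-filter scatter; these blur the penumbra but do not
shift the 50% edge of a symmetric profile, which is why the half-value
full-width edge definition is used throughout.

Aperture decentring (jaw or MLC bank miscalibration) enters the projected
centre with a sign that flips under a 180° collimator rotation, while the
source term does not; the average of the 90° and 270° centres is therefore
miscalibration-free. This cancellation is exact in the point-source model
and is verified to <0.01 mm in simulation for bank errors up to ±1 mm.

Axis bookkeeping: detector `u` runs along columns, `v` along rows, origin
at the grid centre, pixel centres at `(index + 0.5 − N/2)·pitch`. With the
collimator at 90°/270° the X jaws travel along `v` and the Y jaws along
`u`. Reported directions: crossplane = +u; inplane = positive toward the
gun, i.e. −v. The X-jaws→inplane pairing is the default and can be swapped
(`axis_pairing="x-crossplane"`) for head configurations that differ.

## Image algorithm

Per image: (1) 3×3 median filter; (2) global min–max normalisation to
[0, 1]; (3) bicubic upsampling by `round(pitch/0.0392)` — ×20 for 0.784 mm
panels, ×10 for 0.392 mm panels — so every panel reaches the same 0.0392 mm
effective pitch; (4) binarisation at 0.5 (ties belong to the field); (5)
largest connected region, required to cover 1–90% of the frame and not to
touch the border; (6) per row of the central 80% of the field's extent, the
left/right field edges; the centre is the mean of the row midpoints, and
symmetrically for the orthogonal direction.

The edge position within a row is the 50%-intensity crossing, located by
linear interpolation between the pixel just outside the binary region and
the first pixel inside it. A pure extreme-pixel reading quantises each
centre at the 0.0392 mm grid (measured worst case ≈0.01 mm per centre on
noiseless fields, amplified ≈2.4× by `a` after the centroid difference);
the interpolated crossing brings the noiseless single-centre error to
≈0.001 mm while agreeing exactly with the extreme-pixel answer on binary
(hard-edged) fields. Band-averaging over the central 80% (rather than a
single central profile) suppresses noise and keeps MLC corner scallop and
the orthogonal penumbra out of the edge estimate; the fraction is
configurable.

Numerical notes: the 0.5 threshold is applied to min–max scaled
intensities, which coincides with the 50% dose edge only for reasonably
flat fields — adequate for 6 MV 10×10; the binarisation uses `≥` so
exactly-threshold pixels count as field; a constant image raises a
degenerate-image error rather than dividing by zero; upsampling preserves
the centred-origin convention because the resize maps pixel
`j → (j + 0.5)/k − 0.5` in input coordinates.

## Ion-chamber cross-check

A chamber riding on the collimator at `d_ic = 750` mm sits behind a
half-blocking jaw. To first order, charge is linear in how far the jaw
encroaches on the focal spot, so: (1) the sensitivity (nC per mm of jaw
travel at isocenter level) is an OLS slope over a scan of deliberate jaw
shifts — R² < 0.95 triggers a linearity warning; (2) half the 90°−270°
charge difference over the sensitivity is the equivalent iso-level jaw
shift; (3) scaling by `d_jaw/SAD` to the physical jaw plane and by the
similar-triangle lever arm `d_ic/(d_ic − d_jaw)` (1.74 for Y, 2.18 for X)
gives the offset in the same sign convention as the portal-image method.
Output drift between the two deliveries is assumed negligible and is not
corrected.

## Synthetic data

The simulator emulates what the measurement consumes: rectangular
apertures, projected edge-by-edge from their true collimation planes
through the displaced point source, with per-bank aperture errors, an
erf-shaped penumbra with a single detector-plane sigma, pixelation at
0.784 or 0.392 mm, multiplicative Gaussian pixel noise, and 16-bit
quantisation (so written DICOM/PNG fixtures round-trip bit-exactly). MLC
fields use the single MLC distance for both leaf-end and leaf-side edges.
Defaults are the study conditions: 10×10 cm field at isocenter, SID
1000 mm, jaw planes 406/319 mm, MLC 490 mm, chamber 750 mm, penumbra sigma
1 mm (typical of a 6 MV 10×10 edge at the detector), noise 0.5%, 384×512
grid at 0.784 mm.

Not emulated: extra-focal radiation, tongue-and-groove and interleaf
leakage, detector glare/ghosting, beam-profile tilt, jaw/MLC sag with
gantry angle (the method itself is restricted to collimator-only rotation
for the same reason), and EPID arm flex. Passing simulation tests
therefore demonstrates the correctness of the geometry inversion and the
image algorithm's sub-pixel accuracy under idealised image formation, not
robustness to every clinical artefact; the 90°/270° averaging and the
edge-band averaging are the mechanisms that absorb most of those effects
on real images.

The chamber simulator draws charges from the same linear model the
analysis assumes (base − sensitivity × equivalent shift), linearised about
the half-blocked position; second-order obscuration terms are omitted.

## Problem sizes and tolerances

The test suite and the simulator-based acceptance properties run on a
reduced 160×192-pixel grid at 0.784 mm (~125×150 mm of panel) — enough to
hold the projected 10×10 field plus penumbra with margin — and the noise
study uses a 4×4 cm field on an 80×96 grid over 50 seeds per noise level.
On these grids the noiseless pipeline recovers offsets across ±0.5 mm to
<0.005 mm, single-bank ±1 mm miscalibrations move the result <0.01 mm, a
±1 mm SID error moves it <0.002 mm, and the portal-image and chamber
routes agree to <0.02 mm on a common truth — the same bounds hold at the
full 384×512 default, which the worked example in the README uses.
Reported tables round half-away-from-zero to 3 decimal places; all
internal arithmetic is double precision, and reproducibility SDs use the
sample (n−1) denominator, which is what reproduces the published
worked-example rows.

## Design choices

- `project_center` (similar triangles through the offset source) is the
  single source of truth shared by the simulator and the inversion, so the
  forward/inverse loop is exact by construction; it is independently
  validated against a brute-force per-edge ray trace (10⁵ samples per
  edge, agreement to 10⁻⁶ mm) in the tests.
- All internal lengths are mm; geometry YAML may declare `units: cm`.
- The upsample factor is derived from the header pitch, never from the
  panel model — a 512×384 @ 0.784 mm acquisition from an aS1000-equipped
  machine is handled by what the header says.
- Offsets with magnitude ≥5 mm trigger an implausibility warning (not an
  error): such a beam would fail far coarser QA first.
- Action thresholds (e.g. flagging |offset| > 0.1 mm) are deliberately not
  hard-coded; they belong to the department's QA programme, not the
  measurement.
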