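"""Worked-example measurement tables.

Small published-style datasets from a four-linac study (two Clinac 6EX with
aS500 panels, one Clinac 21iX, one TrueBeam): three weekly repeats of the
6 MV focal-spot offset per machine, and the paired portal-image vs
ion-chamber comparison. Useful for demonstrating the reproducibility and
method-agreement statistics without access to a linac.
"""

from __future__ import annotations

import pandas as pd

_LINAC_MODELS = {1: "6EX", 2: "21iX", 3: "6EX", 4: "TrueBeam"}

# Weekly repeats (mm), per linac and reported direction.
_REPRO = {
    (1, "crossplane"): (-0.002, -0.008, -0.006),
    (1, "inplane"): (0.099, 0.084, 0.098),
    (2, "crossplane"): (0.069, 0.087, 0.081),
    (2, "inplane"): (0.021, 0.058, 0.097),
    (3, "crossplane"): (-0.027, -0.026, -0.032),
    (3, "inplane"): (-0.445, -0.419, -0.433),
    (4, "crossplane"): (0.081, 0.082, 0.085),
    (4, "inplane"): (-0.020, -0.018, -0.046),
}

# Same-session offsets (mm) by the two independent methods.
_COMPARISON = [
    (1, "crossplane", -0.005, -0.005),
    (1, "inplane", 0.094, 0.094),
    (2, "crossplane", 0.097, 0.079),
    (2, "inplane", 0.055, 0.059),
    (3, "crossplane", -0.036, -0.029),
    (3, "inplane", -0.458, -0.433),
    (4, "crossplane", 0.106, 0.083),
    (4, "inplane", -0.024, -0.028),
]


def load_reproducibility_example() -> pd.DataFrame:
    """Long-form table of repeated weekly offsets.

    Columns: ``linac`` (1-4), ``model``, ``direction``
    (crossplane/inplane), ``week`` (1-3), ``offset_mm``.
    """
    rows = [
        {
            "linac": linac,
            "model": _LINAC_MODELS[linac],
            "direction": direction,
            "week": week,
            "offset_mm": value,
        }
        for (linac, direction), values in _REPRO.items()
        for week, value in enumerate(values, start=1)
    ]
    return pd.DataFrame(rows)


def load_method_comparison_example() -> pd.DataFrame:
    """Paired ion-chamber vs portal-image offsets on the same four linacs.

    Columns: ``linac``, ``direction``, ``ic_mm``, ``epid_mm``.
    """
    return pd.DataFrame(
        _COMPARISON, columns=["linac", "direction", "ic_mm", "epid_mm"]
    )
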